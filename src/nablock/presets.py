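"""Packaged parameter presets.

``fitted_default()`` returns the shipped default gating parameter set: the
result of fitting the 8 coefficients to the packaged noiseless synthetic
fixture with the default fit configuration.  It is a derived artifact of this
repository (stored with its provenance in ``data/default_fitted_params.json``)
and can be regenerated with ``scripts/refit_default_params.py`` or
:func:`refit_default`.
"""

from __future__ import annotations

import json
from importlib import resources

from .gating import DrugParams, GatingRateParams

__all__ = ["fitted_default", "fitted_default_record", "refit_default",
           "lidocaine"]


def fitted_default_record() -> dict:
    """The stored fit record (parameters, per-dataset SSE, provenance)."""
    ref = resources.files("nablock").joinpath("data/default_fitted_params.json")
    return json.loads(ref.read_text())


def fitted_default() -> GatingRateParams:
    """The packaged default fitted gating parameter set."""
    rec = fitted_default_record()
    return GatingRateParams(**rec["params"])


def lidocaine(concentration_uM: float = 0.0) -> DrugParams:
    """Literature lidocaine binding rates at a given concentration (uM)."""
    return DrugParams(k_on=250.0, k_off=1.7e-3,
                      concentration=concentration_uM * 1e-6)


def refit_default():
    """Re-run the fit that produced the packaged default parameter set."""
    from .fitting import FitConfig, fit_drug_free
    from .fixtures import gen_clamp_fixture

    return fit_drug_free(gen_clamp_fixture(), FitConfig())
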