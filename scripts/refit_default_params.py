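"""Regenerate the packaged default fitted parameter set.

Runs the default fit (8 gating coefficients, packaged noiseless synthetic
fixture, default multistart configuration) and rewrites
``src/nablock/data/default_fitted_params.json`` in place.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from nablock.io import _jsonable  # noqa: E402
from nablock.presets import refit_default  # noqa: E402

TARGET = (Path(__file__).resolve().parents[1]
          / "src/nablock/data/default_fitted_params.json")


def main() -> int:
    result = refit_default()
    record = _jsonable(result.to_dict())
    record["provenance"]["note"] = (
        "fit of the 8 gating coefficients to the packaged noiseless synthetic "
        "fixture (fixtures.gen_clamp_fixture with default FixtureSpec) using "
        "the default FitConfig; regenerate with scripts/refit_default_params.py"
    )
    TARGET.write_text(json.dumps(record, indent=2) + "\n")
    print(f"objective {result.objective:.3e} -> {TARGET}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
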