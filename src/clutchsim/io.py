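"""CSV output with a JSON metadata sidecar.

Every table written by the package gets a ``<name>.json`` sidecar holding
the full parameter set, the seed, the package version, and any documented
assumptions, so a result file is self-describing and reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> Path:
    """Write ``df`` as CSV plus a JSON sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    if metadata is not None:
        sidecar = path.with_suffix(".json")
        with open(sidecar, "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
    return path
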