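"""Small shared helpers: seed fan-out, hashing, table writers."""
from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

# Stage codes for the documented seed fan-out scheme: the global pipeline seed
# and a fixed per-stage code are fed to a SeedSequence, so each stage is
# independently reproducible from (seed, stage name).
STAGE_CODES = {
    "simulate": 1,
    "rarefy": 2,
    "null_preference": 3,
    "null_network": 4,
    "indicators": 5,
    "modularity": 6,
    "rarefaction_curve": 7,
}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a deterministic 31-bit child seed for a named pipeline stage."""
    code = STAGE_CODES[stage]
    ss = np.random.SeedSequence([int(seed), code])
    return int(ss.generate_state(1)[0] % (2**31))


def frame_hash(df: pd.DataFrame) -> str:
    """Content hash of a labelled matrix (values + row/col labels)."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(df.to_numpy()).tobytes())
    h.update("\x1f".join(map(str, df.index)).encode())
    h.update("\x1f".join(map(str, df.columns)).encode())
    return h.hexdigest()


def write_tsv(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        v = float(o)
        return None if np.isnan(v) else v
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)!r}")
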