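"""Plain-CSV persistence with schema/seed header comments.

Every table the pipeline writes is a CSV whose first line is a comment of the
form ``# cgfdist schema=<kind> version=1 seed=<seed>`` so that intermediate
files are diffable and self-describing.  Readers skip comment lines.
"""

from __future__ import annotations

import pandas as pd

HEADER_PREFIX = "# cgfdist"


def write_table(df: pd.DataFrame, path, kind: str, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"{HEADER_PREFIX} schema={kind} version=1 seed={seed}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_header(path) -> dict:
    with open(path) as fh:
        line = fh.readline().strip()
    out = {}
    if line.startswith(HEADER_PREFIX):
        for tok in line.removeprefix(HEADER_PREFIX).split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                out[k] = v
    return out
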