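"""TSV serialization helpers.

All tabular outputs are UTF-8 TSV with a header row, a first column of row
identifiers, "NA" for missing cells (empty cells are also accepted on
read), and floats formatted to 6 significant digits so that repeated runs
hash identically.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.6g"
NA_REP = "NA"


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep=NA_REP, float_format=FLOAT_FORMAT,
              index=True, index_label=df.index.name or "id")
    return path


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0,
                       na_values=["NA", ""], keep_default_na=True)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
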