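"""Versioned TSV artifacts shared by all pipeline stages."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd

TSV_VERSION_HEADER = "#cqkit_tsv_v1"


def write_tsv(df: pd.DataFrame, dest: Union[str, Path]) -> None:
    """Write a DataFrame as TSV with the cqkit version header line."""
    with open(dest, "w") as fh:
        fh.write(TSV_VERSION_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(source: Union[str, Path]) -> pd.DataFrame:
    """Read a cqkit TSV, tolerating (but not requiring) the version header."""
    return pd.read_csv(source, sep="\t", comment="#")
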