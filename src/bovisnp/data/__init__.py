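"""Published reference tables shipped with the package.

Three small TSVs transcribed from the study's printed tables serve as
fixed inputs for table-arithmetic checks and the worked examples:

* ``mapping_profiles.tsv`` — the nine per-breed, per-age mapping
  summaries (ten flagstat counters each);
* ``raw_snpdb_counts.tsv`` — the 18 per-sample raw indel/SNP/total
  counts of the breed-specific raw databases;
* ``reliable_db_counts.tsv`` — per-breed reliable-record and
  error-record counts feeding the error-removal arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..io import read_flagstat_tsv
from ..model import FlagstatProfile


def _path(name: str):
    return resources.files(__package__) / name


def mapping_profiles() -> list[FlagstatProfile]:
    """The nine published per-breed/per-age mapping summaries."""
    with resources.as_file(_path("mapping_profiles.tsv")) as p:
        return read_flagstat_tsv(p)


def raw_snpdb_counts() -> pd.DataFrame:
    """Per-sample raw SNP-db accounting (18 rows)."""
    with resources.as_file(_path("raw_snpdb_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def reliable_db_counts() -> pd.DataFrame:
    """Per-breed reliable-record and error-record counts."""
    with resources.as_file(_path("reliable_db_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")
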