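"""Packaged catalog of the 65 published novel P. trichocarpa miRNAs.

Each record carries the mature sequence, combined read counts printed as
"mature(star)", the precursor location serialized "scaffold:start:end:strand"
(1-based inclusive), the precursor arm hosting the mature, the precursor
length LP in nt, and the published MFOLD precursor energy (MEF, kcal/mol;
fixture data, not recomputed by this package's folding model).
"""

from __future__ import annotations

import re
from importlib import resources

import pandas as pd

_LOCATION_RE = re.compile(r"^(?P<scaffold>[^:]+):(?P<start>\d+):(?P<end>\d+):(?P<strand>[+-])$")


def load_novel_mirna_catalog() -> pd.DataFrame:
    """The 65-record catalog with parsed counts and coordinates.

    Adds columns mature_count, star_count, scaffold, start, end, strand and
    interval_length (= end - start + 1 under the 1-based inclusive
    convention the locations use).
    """
    path = resources.files("plantmir.data").joinpath("novel_mirna_catalog.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    counts = df["counts"].str.extract(r"^(?P<mature_count>\d+)\((?P<star_count>\d+)\)$")
    df["mature_count"] = counts["mature_count"].astype(int)
    df["star_count"] = counts["star_count"].astype(int)
    loc = df["location"].str.extract(_LOCATION_RE)
    df["scaffold"] = loc["scaffold"]
    df["start"] = loc["start"].astype(int)
    df["end"] = loc["end"].astype(int)
    df["strand"] = loc["strand"]
    df["interval_length"] = df["end"] - df["start"] + 1
    return df
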