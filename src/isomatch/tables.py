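"""Packaged study tables: per-individual concordance and cluster posteriors.

Three tables ship with the package as exactly transcribed CSV fixtures
(32 individuals each), guarded by a SHA-256 manifest:

* ``table1``: geographic position, 50%/75% KDE sizes (km^2 and 0.33-degree
  cells), assigned-cell counts for the two- (CN) and three-isotope (HCN)
  assignments at 1:1 and 3:1 odds, and the KDE/assignment overlaps;
* ``table2``: 4-cluster DFA posteriors (HCN) and the cluster composition of
  cells inside each individual's 50% and 75% KDE, as integer percentages;
* ``table3``: the same for the 5-cluster (CN) DFA.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

_DATA = resources.files("isomatch") / "data"


def _load_checked(name: str) -> pd.DataFrame:
    manifest = json.loads((_DATA / "manifest.json").read_text())
    raw = (_DATA / name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if manifest.get(name) != digest:
        raise RuntimeError(f"packaged fixture {name} failed its checksum")
    with (_DATA / name).open() as fh:
        return pd.read_csv(fh)


def fixtures_table1(include_mean_row: bool = False) -> pd.DataFrame:
    """Per-individual KDE sizes, assigned cells and overlaps (32 rows)."""
    df = _load_checked("table1_concordance.csv")
    if not include_mean_row:
        df = df[df["id"] != "mean"].reset_index(drop=True)
        for col in df.columns:
            if col != "id":
                df[col] = pd.to_numeric(df[col])
    return df


def fixtures_table1_mean_row() -> pd.Series:
    """The printed mean row of the concordance table."""
    df = _load_checked("table1_concordance.csv")
    return df[df["id"] == "mean"].iloc[0]


def fixtures_table2() -> pd.DataFrame:
    """4-cluster (HCN) DFA posteriors and KDE cluster compositions."""
    return _load_checked("table2_clusters_hcn.csv")


def fixtures_table3() -> pd.DataFrame:
    """5-cluster (CN) DFA posteriors and KDE cluster compositions."""
    return _load_checked("table3_clusters_cn.csv")
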