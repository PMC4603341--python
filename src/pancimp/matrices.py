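"""Tabular containers for probe- and CGI-level methylation data.

All containers are thin, validated wrappers around :class:`pandas.DataFrame`
so that downstream code can rely on a few invariants (value ranges, index
uniqueness, annotation completeness) without re-checking them at every step.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RELATIONS = ("island", "shore", "shelf", "open_sea")

ANNOTATION_COLUMNS = ["probe_id", "chrom", "pos", "cgi_id", "relation", "genes"]


class ProbeAnnotation:
    """Probe → CGI annotation (450K-manifest-like).

    Parameters
    ----------
    frame : DataFrame with columns ``probe_id, chrom, pos, cgi_id, relation,
        genes``.  ``pos`` is 1-based (manifest convention).  ``cgi_id`` is
        null exactly for ``relation == "open_sea"`` probes.  ``genes`` holds a
        semicolon-separated gene list (may be empty).
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if frame["probe_id"].duplicated().any():
            dups = frame.loc[frame["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValueError(f"duplicate probe ids in annotation: {dups[:5]}")
        bad_rel = set(frame["relation"]) - set(RELATIONS)
        if bad_rel:
            raise ValueError(f"unknown relation values: {sorted(bad_rel)}")
        cgi_null = frame["cgi_id"].isna() | (frame["cgi_id"] == "")
        open_sea = frame["relation"] == "open_sea"
        if (cgi_null != open_sea).any():
            raise ValueError("cgi_id must be null exactly for open_sea probes")
        frame.loc[cgi_null, "cgi_id"] = pd.NA
        frame["genes"] = frame["genes"].fillna("")
        self.frame = frame.set_index("probe_id", drop=False)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def probe_ids(self) -> pd.Index:
        return self.frame.index

    def cgi_genes(self) -> pd.Series:
        """Semicolon-joined union of gene symbols per CGI (empty = unannotated)."""
        ann = self.frame.dropna(subset=["cgi_id"])
        def _union(vals):
            genes = sorted({g for v in vals for g in str(v).split(";") if g})
            return ";".join(genes)
        return ann.groupby("cgi_id")["genes"].agg(_union)

    @classmethod
    def read_csv(cls, path) -> "ProbeAnnotation":
        return cls(pd.read_csv(path, dtype={"chrom": str}))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class ProbeBetaMatrix:
    """Probe × sample methylation fractions (beta values), NaN = missing."""

    beta: pd.DataFrame

    def __post_init__(self):
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if self.beta.index.duplicated().any() or self.beta.columns.duplicated().any():
            raise ValueError("probe and sample ids must be unique")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @classmethod
    def read_tsv(cls, path) -> "ProbeBetaMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.beta.to_csv(path, sep="\t", index_label="probe_id")


@dataclass
class CgiBetaMatrix:
    """CGI × sample aggregated methylation with per-CGI probe counts."""

    beta: pd.DataFrame
    n_probes: pd.Series = field(default=None)

    def __post_init__(self):
        if self.n_probes is None:
            self.n_probes = pd.Series(1, index=self.beta.index)
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("aggregated beta values must lie in [0, 1]")
        if (self.n_probes.reindex(self.beta.index) < 1).any():
            raise ValueError("every CGI needs >= 1 contributing probe")

    @property
    def cgi_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @classmethod
    def read_tsv(cls, path) -> "CgiBetaMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.beta.to_csv(path, sep="\t", index_label="cgi_id")
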