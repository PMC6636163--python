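"""Two-pass detection of segregating non-reference TE insertions.

The caller consumes a per-accession read-evidence table (discordant and
split read counts at candidate sites) rather than alignments.  Discovery
first requires at least ``min_support`` (default 10) combined supporting
reads in any one accession; presence/absence is then genotyped across the
population with a relaxed threshold (default 2), which recovers insertions
shared by several accessions that individually fall short of the discovery
bar.  The target-site-duplication flag is carried through and reported but
is not a calling criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InsertionEvidence",
    "InsertionCallSet",
    "read_evidence",
    "filter_low_coverage_accessions",
    "discover_insertions",
    "genotype_population",
]

_REQUIRED = [
    "accession_id", "scaffold", "position", "te_family",
    "discordant_reads", "split_reads",
]


@dataclass(frozen=True)
class InsertionEvidence:
    accession_id: str
    scaffold: str
    position: int
    te_family: str
    discordant_reads: int
    split_reads: int
    tsd_present: bool = False

    def __post_init__(self) -> None:
        if self.discordant_reads < 0 or self.split_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def support(self) -> int:
        return self.discordant_reads + self.split_reads


@dataclass
class InsertionCallSet:
    """Candidate sites x accessions presence matrix plus composition."""

    sites: list[tuple[str, int, str]]          # (scaffold, position, family)
    presence: pd.DataFrame                     # bool, index=site label, cols=accessions
    min_support: int
    tsd_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def frequency_spectrum(self) -> pd.Series:
        return self.presence.sum(axis=1).value_counts().sort_index()

    @property
    def superfamily_composition(self) -> pd.Series:
        fams = pd.Series([f for _, _, f in self.sites], dtype=object)
        comp = fams.value_counts(normalize=True).sort_index()
        return comp


def filter_low_coverage_accessions(
    evidence: pd.DataFrame, min_mean_support: float
) -> pd.DataFrame:
    """Drop accessions whose mean combined read support is below the floor.

    Mirrors the practice of excluding low-coverage samples from population
    genotyping; off by default in all callers.
    """
    support = evidence["discordant_reads"] + evidence["split_reads"]
    means = support.groupby(evidence["accession_id"]).mean()
    keep = set(means[means >= min_mean_support].index)
    return evidence[evidence["accession_id"].isin(keep)].reset_index(drop=True)


def read_evidence(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"evidence table missing column(s): {missing}")
    if "tsd_present" not in df.columns:
        df["tsd_present"] = False
    return df


def _dedupe_sites(rows: pd.DataFrame, tolerance: int) -> pd.DataFrame:
    """Merge candidate sites of the same family within a positional window.

    The best-supported site of each cluster becomes the representative.
    """
    out = []
    for (sc, fam), grp in rows.groupby(["scaffold", "te_family"], sort=True):
        grp = grp.sort_values(["position", "max_support"], kind="mergesort")
        cluster: list[pd.Series] = []
        last = None
        for _, row in grp.iterrows():
            if last is not None and row["position"] - last > tolerance:
                out.append(max(cluster, key=lambda r: (r["max_support"], -r["position"])))
                cluster = []
            cluster.append(row)
            last = row["position"]
        if cluster:
            out.append(max(cluster, key=lambda r: (r["max_support"], -r["position"])))
    return pd.DataFrame(out).reset_index(drop=True)


def discover_insertions(
    evidence: pd.DataFrame, min_support: int = 10, dedupe_tolerance: int = 100
) -> pd.DataFrame:
    """De novo discovery pass: sites reaching ``min_support`` combined reads
    (discordant + split) in at least one accession, deduplicated within
    ``dedupe_tolerance`` bp per scaffold and family."""
    ev = evidence.copy()
    ev["support"] = ev["discordant_reads"] + ev["split_reads"]
    per_site = (
        ev.groupby(["scaffold", "position", "te_family"], sort=True)["support"]
        .max()
        .reset_index()
        .rename(columns={"support": "max_support"})
    )
    candidates = per_site[per_site["max_support"] >= min_support]
    if candidates.empty:
        return candidates.assign(site_id=pd.Series(dtype=str))
    merged = _dedupe_sites(candidates, dedupe_tolerance)
    merged["site_id"] = [
        f"{r.scaffold}:{r.position}:{r.te_family}" for r in merged.itertuples()
    ]
    return merged


def genotype_population(
    candidates: pd.DataFrame,
    evidence: pd.DataFrame,
    min_support: int = 2,
    dedupe_tolerance: int = 100,
) -> InsertionCallSet:
    """Genotyping pass: per candidate site and accession, present iff the
    combined read support within the positional window reaches ``min_support``."""
    accessions = sorted(evidence["accession_id"].unique())
    ev = evidence.copy()
    ev["support"] = ev["discordant_reads"] + ev["split_reads"]
    sites = []
    rows = []
    tsd_fraction = {}
    for r in candidates.itertuples():
        sel = ev[
            (ev["scaffold"] == r.scaffold)
            & (ev["te_family"] == r.te_family)
            & ((ev["position"] - r.position).abs() <= dedupe_tolerance)
        ]
        per_acc = sel.groupby("accession_id")["support"].sum()
        present = {a: bool(per_acc.get(a, 0) >= min_support) for a in accessions}
        sites.append((r.scaffold, int(r.position), r.te_family))
        rows.append(present)
        with_tsd = sel[sel.get("tsd_present", False) == True]  # noqa: E712
        tsd_fraction[r.site_id] = (
            float(len(with_tsd["accession_id"].unique()) / max(1, len(per_acc)))
        )
    index = [f"{sc}:{pos}:{fam}" for sc, pos, fam in sites]
    presence = pd.DataFrame(rows, index=index, columns=accessions).fillna(False)
    return InsertionCallSet(sites, presence, min_support, tsd_fraction)
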