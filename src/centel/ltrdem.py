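"""LTR-RT demography: intact/solo/truncated classification, scaffold
filtering, S:I / T:I ratio summaries, LTR clustering and high-death-rate
family calling.

Classification rules: a locus whose internal evidence covers the complete
Gag-Pol polyprotein (domains GAG, PR, RT, RH, INT present in order) is intact
(I); otherwise a single one-sided hit with coverage >= 50% of a Gag-Pol
reference, E-value < 1e-8 and identity > 30% makes it truncated (T); LTRs
with no Gag-Pol evidence are solo (S). Solo:intact ratios proxy element
removal; per-cluster S:I above a threshold (default 3) flags a family as
having a high death rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Hit, LTRLocus
from .tenet import alignment_identity_coverage, make_aligner

__all__ = [
    "GAGPOL_DOMAINS",
    "classify_ltr_locus",
    "classify_all",
    "filter_by_scaffold",
    "demography_ratios",
    "cluster_ltrs",
    "high_death_fraction",
    "DemographyReport",
    "demography_report",
]

GAGPOL_DOMAINS = ("GAG", "PR", "RT", "RH", "INT")

TRUNCATED_MIN_COVERAGE = 0.50  # inclusive ("at least 50%")
TRUNCATED_MAX_EVALUE = 1e-8  # exclusive ("< 1E-8")
TRUNCATED_MIN_IDENTITY = 30.0  # exclusive ("> 30%")


def _is_subsequence(needle: tuple[str, ...], haystack: list[str]) -> bool:
    it = iter(haystack)
    return all(any(x == want for x in it) for want in needle)


def classify_ltr_locus(
    locus: LTRLocus,
    required_domains: tuple[str, ...] = GAGPOL_DOMAINS,
) -> str:
    """Classify one locus as I, T or S from its hit evidence (idempotent,
    order-independent across loci)."""
    for h in locus.hits:
        if not isinstance(h, Hit):
            raise ValueError(f"malformed hit row on {locus.locus_id}: {h!r}")
    internal_domains: list[str] = []
    for h in locus.hits:
        if h.side == "internal":
            internal_domains.extend(h.domains)
    if _is_subsequence(required_domains, internal_domains):
        return "I"
    for h in locus.hits:
        if (
            h.side in ("left", "right")
            and h.coverage >= TRUNCATED_MIN_COVERAGE
            and h.evalue < TRUNCATED_MAX_EVALUE
            and h.identity > TRUNCATED_MIN_IDENTITY
        ):
            return "T"
    return "S"


def classify_all(loci: list[LTRLocus]) -> dict[str, int]:
    """Classify every locus in place; returns class counts (partition)."""
    counts = {"I": 0, "S": 0, "T": 0}
    for locus in loci:
        locus.class_label = classify_ltr_locus(locus)
        counts[locus.class_label] += 1
    assert sum(counts.values()) == len(loci)
    return counts


def filter_by_scaffold(loci: list[LTRLocus], min_scaffold_len: int = 1_000_000) -> list[LTRLocus]:
    """Keep loci on scaffolds >= ``min_scaffold_len`` (fragmented scaffolds
    bias class counts; monotone: raising the threshold never adds loci)."""
    return [lc for lc in loci if lc.scaffold_length >= min_scaffold_len]


def demography_ratios(n_i: int, n_s: int, n_t: int) -> dict[str, float]:
    """S:I, T:I and (S+T):I to two decimals, plus the birth-rate proxy
    I + S + T. Undefined (NaN) when I = 0."""
    total = n_i + n_s + n_t
    if n_i <= 0:
        return {
            "S:I": float("nan"),
            "T:I": float("nan"),
            "(S+T):I": float("nan"),
            "I+S+T": total,
        }
    return {
        "S:I": round(n_s / n_i, 2),
        "T:I": round(n_t / n_i, 2),
        "(S+T):I": round((n_s + n_t) / n_i, 2),
        "I+S+T": total,
    }


def _kmer_set(seq: str, k: int = 12) -> set[str]:
    return {seq[i : i + k] for i in range(0, len(seq) - k + 1)}


def cluster_ltrs(
    loci: list[LTRLocus],
    min_coverage: float = 0.70,
    min_identity: float = 0.60,
    min_shared_kmers: int = 3,
) -> dict[str, int]:
    """Single-linkage clustering of LTR sequences at the given coverage and
    identity thresholds (both must hold for a link).

    Both LTRs of an intact locus contribute to linkage; the cluster of a
    locus is the cluster of its 5' LTR. Deterministic: clusters are numbered
    by their lexicographically smallest member sequence key. Pairs sharing
    fewer than ``min_shared_kmers`` exact 12-mers are treated as unlinked
    without alignment (a seed-and-extend style screen; any pair meeting the
    identity threshold over >= 70% of the shorter sequence shares many exact
    12-mers with overwhelming probability).
    """
    seqs: dict[str, str] = {}
    owner: dict[str, str] = {}
    for lc in loci:
        if lc.ltr5_seq:
            key = f"{lc.locus_id}/5"
            seqs[key] = lc.ltr5_seq
            owner[key] = lc.locus_id
        if lc.ltr3_seq:
            seqs[f"{lc.locus_id}/3"] = lc.ltr3_seq
    keys = sorted(seqs)
    parent = {k: k for k in keys}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            if ry < rx:
                rx, ry = ry, rx
            parent[ry] = rx

    aligner = make_aligner()
    kmers = {k: _kmer_set(seqs[k]) for k in keys}
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            if find(a) == find(b):
                continue  # transitive closure: already linked
            if len(kmers[a] & kmers[b]) < min_shared_kmers:
                continue
            ident, cov = alignment_identity_coverage(seqs[a], seqs[b], aligner)
            if cov >= min_coverage and ident >= min_identity:
                union(a, b)

    roots = sorted({find(k) for k in keys})
    root_id = {r: i for i, r in enumerate(roots)}
    assignment: dict[str, int] = {}
    for key, locus_id in owner.items():
        assignment[locus_id] = root_id[find(key)]
    for lc in loci:
        lc.cluster_id = assignment.get(lc.locus_id)
    return assignment


def high_death_fraction(
    cluster_classes: pd.DataFrame, threshold: float = 3.0
) -> tuple[float, pd.DataFrame]:
    """Fraction of clusters with S:I above ``threshold``.

    ``cluster_classes`` columns: cluster, I, S (counts). Clusters with I = 0
    and S > 0 count as high-death (infinite ratio); clusters with I = S = 0
    are excluded from the denominator.
    """
    df = cluster_classes.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        df["S:I"] = np.where(df["I"] > 0, df["S"] / df["I"], np.inf)
    evaluable = (df["I"] > 0) | (df["S"] > 0)
    df["evaluable"] = evaluable
    df["high_death"] = evaluable & (df["S:I"] > threshold)
    n_eval = int(evaluable.sum())
    frac = float(df["high_death"].sum() / n_eval) if n_eval else 0.0
    return frac, df


@dataclass
class DemographyReport:
    """I/S/T counts (raw and scaffold-filtered), ratio summaries and the
    per-cluster high-death table."""

    counts_raw: dict[str, int]
    counts_filtered: dict[str, int]
    ratios_raw: dict[str, float]
    ratios_filtered: dict[str, float]
    min_scaffold_len: int
    death_threshold: float
    cluster_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    high_death_fraction: float = float("nan")


def demography_report(
    loci: list[LTRLocus],
    min_scaffold_len: int = 1_000_000,
    death_threshold: float = 3.0,
    do_cluster: bool = True,
) -> DemographyReport:
    """Full demography summary: classify, filter, ratio, cluster, call
    high-death families (clusters computed on the scaffold-filtered set)."""
    counts_raw = classify_all(loci)
    kept = filter_by_scaffold(loci, min_scaffold_len)
    counts_f = {"I": 0, "S": 0, "T": 0}
    for lc in kept:
        counts_f[lc.class_label] += 1
    report = DemographyReport(
        counts_raw=counts_raw,
        counts_filtered=counts_f,
        ratios_raw=demography_ratios(counts_raw["I"], counts_raw["S"], counts_raw["T"]),
        ratios_filtered=demography_ratios(counts_f["I"], counts_f["S"], counts_f["T"]),
        min_scaffold_len=min_scaffold_len,
        death_threshold=death_threshold,
    )
    if do_cluster and kept:
        cluster_ltrs(kept)
        rows: dict[int, dict[str, int]] = {}
        for lc in kept:
            if lc.cluster_id is None:
                continue
            row = rows.setdefault(lc.cluster_id, {"I": 0, "S": 0, "T": 0})
            row[lc.class_label] += 1
        table = pd.DataFrame(
            [{"cluster": cid, **counts} for cid, counts in sorted(rows.items())]
        )
        frac, table = high_death_fraction(table, death_threshold)
        report.cluster_table = table
        report.high_death_fraction = frac
    return report
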