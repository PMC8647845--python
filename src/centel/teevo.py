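"""Intact-element screening, K2P divergence, insertion dating and
compartment statistics.

Insertion times follow the LTR/best-hit dating convention: the two LTRs of a
retrotransposon are identical at insertion and diverge independently
afterwards, so their Kimura two-parameter distance K converts to an age
T = K / (2 r) with r the per-site yearly substitution rate (default
1.3e-8 /site/yr).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import CentromereRegion, DivergenceEstimate, ElementRecord, LTRLocus, OrfRecord

__all__ = [
    "SaturationError",
    "find_orfs",
    "classify_intact_line1",
    "k2p_divergence",
    "insertion_time",
    "date_elements",
    "RankSumResult",
    "rank_sum_test",
    "compare_compartments",
]

DEFAULT_RATE = 1.3e-8  # substitutions / site / year
DEFAULT_MIN_ORF = 800  # nt, getorf-style "-minsize 800"

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


class SaturationError(ValueError):
    """K2P distance undefined: a log argument is <= 0 (saturated pair)."""


# ---------------------------------------------------------------------------
# ORFs and intact LINE1
# ---------------------------------------------------------------------------

def find_orfs(
    sequence: str, min_len: int = DEFAULT_MIN_ORF, element_id: str = ""
) -> list[OrfRecord]:
    """Start-to-stop ORFs of length >= ``min_len`` nt on both strands.

    Scans all six frames; an ORF opens at the first ATG after the previous
    stop (or after an ambiguous codon) and closes at the next in-frame stop.
    Codons containing N break and reset the scan. Reported length excludes
    the stop codon; coordinates are 1-based on the forward strand.
    """
    seq = sequence.upper()
    n = len(seq)
    out: list[OrfRecord] = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else seq.translate(_COMP)[::-1]
        for frame in range(3):
            start_pos: int | None = None
            for i in range(frame, n - 2, 3):
                codon = s[i : i + 3]
                if "N" in codon:
                    start_pos = None
                    continue
                if start_pos is None:
                    if codon == "ATG":
                        start_pos = i
                    continue
                if codon in _STOPS:
                    length = i - start_pos
                    if length >= min_len:
                        if strand == "+":
                            a, b = start_pos + 1, i  # excludes stop codon
                        else:
                            a, b = n - i + 1, n - start_pos
                        out.append(
                            OrfRecord(
                                element_id=element_id,
                                strand=strand,
                                frame=frame,
                                start=a,
                                end=b,
                                length=length,
                                orf_id=f"{element_id}:{strand}{frame}:{a}",
                            )
                        )
                    start_pos = None
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def classify_intact_line1(
    element_id: str,
    orfs: list[OrfRecord],
    domain_hits: pd.DataFrame,
    rt_labels: tuple[str, ...] = ("RT", "RVT", "RVT_1", "RVT_3"),
    en_labels: tuple[str, ...] = ("EN", "Exo_endo_phos", "Endonuclease"),
) -> bool:
    """A LINE1 is intact iff at least one qualifying ORF carries a
    reverse-transcriptase domain and at least one an endonuclease domain
    (possibly the same ORF). ``domain_hits`` columns: element, orf, domain."""
    known = {o.orf_id for o in orfs}
    mine = domain_hits[domain_hits["element"] == element_id]
    unknown = set(mine["orf"]) - known
    if unknown:
        raise ValueError(f"hits reference unknown ORFs: {sorted(unknown)}")
    if not orfs:
        return False
    doms = set(mine["domain"])
    return bool(doms & set(rt_labels)) and bool(doms & set(en_labels))


# ---------------------------------------------------------------------------
# K2P divergence and insertion time
# ---------------------------------------------------------------------------

_PURINES = {"A", "G"}


def k2p_divergence(seq_a: str, seq_b: str) -> DivergenceEstimate:
    """Kimura two-parameter distance between two aligned sequences.

    Gap and ambiguous columns are excluded from the site count.
    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P and Q the transition and
    transversion proportions. Raises :class:`SaturationError` when a log
    argument is <= 0.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = seq_a.upper()
    b = seq_b.upper()
    sites = ts = tv = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if sites == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / sites, tv / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"saturated pair: P={P:.3f}, Q={Q:.3f} (log arguments {w1:.3f}, {w2:.3f})"
        )
    K = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return DivergenceEstimate(P=P, Q=Q, K=K, sites=sites)


def insertion_time(K: float, rate: float = DEFAULT_RATE) -> float:
    """Insertion age in years: T = K / (2 r)."""
    if K < 0:
        raise ValueError("K must be >= 0")
    if rate <= 0:
        raise ValueError("substitution rate must be > 0")
    return K / (2.0 * rate)


def _align_pair(a: str, b: str) -> tuple[str, str]:
    """Global alignment of two sequences (exact edit-distance DP)."""
    import edlib

    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    return nice["query_aligned"], nice["target_aligned"]


def date_elements(
    loci: list[LTRLocus] | None = None,
    pairs: dict[str, tuple[str, str]] | None = None,
    mode: str = "ltr_pair",
    rate: float = DEFAULT_RATE,
) -> pd.DataFrame:
    """Per-element K2P divergence and insertion time.

    ``ltr_pair`` mode dates each locus by its 5'/3' LTR pair; ``best_hit``
    mode takes explicit sequence pairs (element vs its assigned partner).
    Elements failing alignment or saturated are flagged in the ``status``
    column, never silently dropped.
    """
    if mode == "ltr_pair":
        if loci is None:
            raise ValueError("ltr_pair mode needs loci")
        items = [(lc.locus_id, lc.ltr5_seq, lc.ltr3_seq) for lc in loci]
    elif mode == "best_hit":
        if pairs is None:
            raise ValueError("best_hit mode needs pairs")
        items = [(eid, a, b) for eid, (a, b) in pairs.items()]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rows = []
    for eid, a, b in items:
        if not a or not b:
            rows.append(
                dict(element=eid, P=np.nan, Q=np.nan, K=np.nan, sites=0,
                     t_mya=np.nan, status="missing_partner")
            )
            continue
        aln_a, aln_b = (a, b) if len(a) == len(b) and "-" not in a + b else _align_pair(a, b)
        if len(aln_a) != len(aln_b):
            aln_a, aln_b = _align_pair(a, b)
        try:
            est = k2p_divergence(aln_a, aln_b)
        except SaturationError:
            rows.append(
                dict(element=eid, P=np.nan, Q=np.nan, K=np.nan, sites=len(aln_a),
                     t_mya=np.nan, status="saturated")
            )
            continue
        t = insertion_time(est.K, rate)
        rows.append(
            dict(element=eid, P=est.P, Q=est.Q, K=est.K, sites=est.sites,
                 t_mya=t / 1e6, status="ok")
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rank-sum test and compartment comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    U: float
    z: float
    p: float
    degenerate: bool = False


EXACT_MAX_N = 8  # exact permutation distribution when both groups are this small


def _exact_p(ranks: np.ndarray, n1: int, U: float, alternative: str) -> float:
    """Tie-aware exact permutation p over all C(n, n1) group splits."""
    from itertools import combinations

    n = len(ranks)
    mean_u = n1 * (n - n1) / 2.0
    obs = abs(U - mean_u)
    offset = n1 * (n1 + 1) / 2.0
    count = total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if alternative == "two-sided":
            count += abs(u - mean_u) >= obs - 1e-9
        elif alternative == "greater":
            count += u >= U - 1e-9
        else:
            count += u <= U + 1e-9
    return count / total


def rank_sum_test(
    group_a, group_b, alternative: str = "two-sided", method: str = "auto"
) -> RankSumResult:
    """Mann-Whitney U rank-sum test via midranks.

    U is reported for group A. ``method='normal'`` uses the tie-corrected
    normal approximation with a 0.5 continuity correction toward the null
    mean; ``method='exact'`` enumerates the tie-aware permutation
    distribution of U; ``'auto'`` picks exact when both groups have at most
    8 observations. When every value is identical across both groups the
    test is degenerate: p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    U = r1 - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return RankSumResult(U=U, z=0.0, p=1.0, degenerate=True)
    if method == "auto":
        method = "exact" if max(n1, n2) <= EXACT_MAX_N else "normal"
    if method == "exact":
        p = _exact_p(ranks, n1, U, alternative)
        z = (U - mean_u) / math.sqrt(var_u)
        return RankSumResult(U=float(U), z=float(z), p=float(p))
    if method != "normal":
        raise ValueError(f"unknown method {method!r}")
    diff = U - mean_u
    if alternative == "two-sided":
        z = math.copysign(max(abs(diff) - 0.5, 0.0), diff) / math.sqrt(var_u)
        p = 2.0 * sps.norm.sf(abs(z))
    elif alternative == "greater":
        z = (diff - 0.5) / math.sqrt(var_u)
        p = sps.norm.sf(z)
    elif alternative == "less":
        z = (diff + 0.5) / math.sqrt(var_u)
        p = sps.norm.cdf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return RankSumResult(U=float(U), z=float(z), p=float(min(p, 1.0)))


def compare_compartments(
    elements: list[ElementRecord],
    regions: list[CentromereRegion],
    dates: dict[str, float] | None = None,
    alternative: str = "two-sided",
    min_group: int = 2,
) -> pd.DataFrame:
    """Per-family centromeric vs non-centromeric comparison of element
    lengths and (optionally) insertion times.

    Compartment membership uses the midpoint rule. Families with fewer than
    ``min_group`` elements on either side are flagged and carry no test.
    """
    by_chrom: dict[str, list[CentromereRegion]] = {}
    for r in regions:
        if not r.flagged:
            by_chrom.setdefault(r.chrom, []).append(r)

    fam_data: dict[str, dict[str, list[float]]] = {}
    for el in elements:
        inside = any(r.contains(el.midpoint) for r in by_chrom.get(el.chrom, ()))
        d = fam_data.setdefault(
            el.family,
            {"len_in": [], "len_out": [], "age_in": [], "age_out": []},
        )
        d["len_in" if inside else "len_out"].append(el.length)
        if dates is not None and el.element_id in dates:
            age = dates[el.element_id]
            if age is not None and np.isfinite(age):
                d["age_in" if inside else "age_out"].append(age)

    rows = []
    for fam, d in sorted(fam_data.items()):
        row: dict[str, object] = {
            "family": fam,
            "n_in": len(d["len_in"]),
            "n_out": len(d["len_out"]),
            "len_median_in": float(np.median(d["len_in"])) if d["len_in"] else np.nan,
            "len_median_out": float(np.median(d["len_out"])) if d["len_out"] else np.nan,
            "len_U": np.nan,
            "len_p": np.nan,
            "age_median_in": np.nan,
            "age_median_out": np.nan,
            "age_U": np.nan,
            "age_p": np.nan,
            "flagged": False,
        }
        if len(d["len_in"]) < min_group or len(d["len_out"]) < min_group:
            row["flagged"] = True
        else:
            res = rank_sum_test(d["len_in"], d["len_out"], alternative)
            row["len_U"], row["len_p"] = res.U, res.p
        if dates is not None:
            if d["age_in"]:
                row["age_median_in"] = float(np.median(d["age_in"]))
            if d["age_out"]:
                row["age_median_out"] = float(np.median(d["age_out"]))
            if len(d["age_in"]) >= min_group and len(d["age_out"]) >= min_group:
                res = rank_sum_test(d["age_in"], d["age_out"], alternative)
                row["age_U"], row["age_p"] = res.U, res.p
            elif not row["flagged"]:
                row["flagged"] = True
        rows.append(row)
    return pd.DataFrame(rows)
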