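"""Seeded simulation of genomes, TE annotations, Hi-C maps and LTR-RT loci.

The generator produces the statistical structure the downstream analysis
assumes: per-chromosome TE landscapes with LINE1/Gypsy enrichment confined to
one narrow centromeric region per chromosome, gene depletion and elevated GC
there, Hi-C cis contacts with power-law distance decay plus trans-contact
concentration at centromere pairs (Poisson counts), and LTR-RT loci in
intact/solo/truncated proportions whose paired LTRs diverge according to the
chosen insertion age at a substitution rate r (default 1.3e-8 per site per
year).

Everything is deterministic given ``SimConfig.seed``; the three top-level
operations draw from independent streams spawned from that seed, so they can
be called in any order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ContactMap, ElementRecord, GenomeModel, Hit, LTRLocus

import pandas as pd

__all__ = [
    "FamilyConfig",
    "SimConfig",
    "DEMO_FAMILY_MIX",
    "simulate_genome",
    "simulate_hic",
    "simulate_ltr_loci",
    "k2p_substitution_probs",
    "mutate_sequence",
    "expected_pair_identity",
]

_BASES = np.frombuffer(b"AGCT", dtype="S1")  # order: transitions are 0<->1, 2<->3


# ---------------------------------------------------------------------------
# K2P mutation machinery (shared by element sequences and LTR pairs)
# ---------------------------------------------------------------------------

def k2p_substitution_probs(d: float, kappa: float) -> tuple[float, float, float]:
    """Per-site outcome probabilities after ``d`` expected substitutions/site.

    Kimura two-parameter process with transition:transversion rate ratio
    ``kappa`` = alpha/(2 beta). Returns (p_same, p_transition,
    p_transversion_total). ``kappa`` = 0.5 recovers Jukes-Cantor.
    """
    if d < 0:
        raise ValueError("branch length must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    a = d * kappa / (kappa + 1.0)  # alpha * t
    b = d / (2.0 * (kappa + 1.0))  # beta * t
    e1 = math.exp(-4.0 * b)
    e2 = math.exp(-2.0 * (a + b))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.5 - 0.5 * e1
    return 1.0 - p_ts - p_tv, p_ts, p_tv


def expected_pair_identity(age_mya: float, rate: float, kappa: float) -> float:
    """Expected fraction of identical sites between two LTRs of age ``age_mya``."""
    d_pair = 2.0 * rate * age_mya * 1e6
    p_same, _, _ = k2p_substitution_probs(d_pair, kappa)
    return p_same


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    codes = np.full(len(arr), -1, dtype=np.int8)
    for i, base in enumerate(_BASES):
        codes[arr == base] = i
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def mutate_sequence(seq: str, d: float, kappa: float, rng: np.random.Generator) -> str:
    """Evolve ``seq`` for ``d`` expected substitutions/site under K2P."""
    codes = _encode(seq)
    p_same, p_ts, _ = k2p_substitution_probs(d, kappa)
    u = rng.random(len(codes))
    out = codes.copy()
    ts = (u >= p_same) & (u < p_same + p_ts)
    out[ts] ^= 1  # A<->G, C<->T
    tv = u >= p_same + p_ts
    if tv.any():
        # purines go to a random pyrimidine and vice versa
        flip = rng.integers(0, 2, size=int(tv.sum())).astype(np.int8)
        out[tv] = ((codes[tv] < 2).astype(np.int8) * 2) + flip
    return _decode(out)


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A G C T
    return _decode(rng.choice(4, size=length, p=p).astype(np.int8))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyConfig:
    """Two-compartment landscape model for one element family.

    Densities are elements per Mb; lengths are log-normal in bp; ages are
    log-normal in MYA. ``cen_subfamily_divergence`` > 0 gives centromeric
    copies their own consensus (a centromere-specific subfamily), derived from
    the family consensus at that divergence.
    """

    density_in: float  # elements / Mb inside the centromeric region
    density_out: float
    len_median_in: float = 2000.0
    len_median_out: float = 2000.0
    len_sdlog: float = 0.35
    age_median_in: float = 1.0  # MYA
    age_median_out: float = 1.0
    age_sdlog: float = 0.5
    has_sequence: bool = True
    consensus_length: int = 8000
    cen_subfamily_divergence: float = 0.0
    gc_in: float = 0.44
    gc_out: float = 0.36


def _default_families() -> dict[str, FamilyConfig]:
    # Defaults emulate the yellowhorn landscape: LINE1 and Gypsy concentrated
    # in and recently active within the centromere (ages ~0.7 MYA), Copia
    # uniform and older inside, genes depleted inside.
    return {
        "LINE1": FamilyConfig(
            density_in=60.0, density_out=4.0,
            len_median_in=3000.0, len_median_out=1500.0,
            age_median_in=0.7, age_median_out=2.0,
            cen_subfamily_divergence=0.20,
        ),
        "Gypsy": FamilyConfig(
            density_in=40.0, density_out=12.0,
            len_median_in=5000.0, len_median_out=3500.0,
            age_median_in=0.66, age_median_out=2.0,
            cen_subfamily_divergence=0.15,
        ),
        "Copia": FamilyConfig(
            density_in=12.0, density_out=12.0,
            len_median_in=4000.0, len_median_out=4000.0,
            age_median_in=1.36, age_median_out=0.9,
            cen_subfamily_divergence=0.0,
        ),
        "gene": FamilyConfig(
            density_in=2.0, density_out=20.0,
            len_median_in=2500.0, len_median_out=2500.0,
            has_sequence=False,
        ),
    }


@dataclass(frozen=True)
class SimConfig:
    """All simulation parameters; ``seed`` controls every random draw."""

    chrom_lengths: tuple[int, ...] = (5_000_000,) * 5
    bin_size: int = 100_000
    centromere_width: int = 500_000
    families: dict[str, FamilyConfig] = field(default_factory=_default_families)
    # molecular evolution
    rate: float = 1.3e-8  # substitutions / site / year
    kappa: float = 2.0  # transition:transversion rate ratio
    # Hi-C
    hic_alpha: float = 1.0  # cis power-law decay exponent
    hic_cis_scale: float = 100.0  # expected cis count at 1-bin separation
    hic_trans_background: float = 0.5  # expected trans count per bin pair
    hic_bump: float = 10.0  # extra expected count at the centromere pair
    hic_sigma: float = 1.5  # bump bandwidth, bins
    # LTR-RT demography
    n_ltr_loci: int = 300
    ist_proportions: tuple[float, float, float] = (0.13, 0.21, 0.66)
    ltr_age_mya: float | None = None  # None -> draw from log-normal below
    ltr_age_median: float = 1.0
    ltr_age_sdlog: float = 0.6
    ltr_len_median: float = 800.0
    ltr_len_sdlog: float = 0.30
    n_ltr_families: int = 6
    # per-family (pI, pS, pT); None -> derived from ist_proportions with the
    # last two families solo-heavy (high death-rate, S:I > 3)
    ltr_family_mix: tuple[tuple[float, float, float], ...] | None = None
    ltr_intra_family_divergence: float = 0.05
    short_scaffold_fraction: float = 0.15
    short_scaffold_length: int = 400_000
    long_scaffold_length: int = 10_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(L < 2 * self.bin_size for L in self.chrom_lengths):
            raise ValueError("every chromosome must be >= 2 x bin_size")
        if any(self.centromere_width >= L for L in self.chrom_lengths):
            raise ValueError("centromere width must be < chromosome length")
        if self.hic_alpha <= 0 or self.hic_sigma <= 0:
            raise ValueError("hic_alpha and hic_sigma must be > 0")
        for v in (self.hic_cis_scale, self.hic_trans_background, self.hic_bump):
            if v < 0 or not math.isfinite(v):
                raise ValueError("Hi-C intensities must be finite and >= 0")
        if abs(sum(self.ist_proportions) - 1.0) > 1e-9 or min(self.ist_proportions) < 0:
            raise ValueError("I/S/T proportions must be >= 0 and sum to 1")
        if self.rate <= 0:
            raise ValueError("substitution rate must be > 0")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"Chr{i + 1:02d}" for i in range(len(self.chrom_lengths)))

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


_STREAM_GENOME, _STREAM_HIC, _STREAM_LTR = 1, 2, 3


# ---------------------------------------------------------------------------
# Genome + annotation simulation
# ---------------------------------------------------------------------------

def _draw_centromeres(config: SimConfig, rng: np.random.Generator) -> dict[str, int]:
    mids = {}
    for name, length in zip(config.chrom_names, config.chrom_lengths):
        half = config.centromere_width // 2
        # keep the full region inside the chromosome
        mids[name] = int(rng.integers(half + 1, length - half))
    return mids


def simulate_genome(config: SimConfig) -> tuple[GenomeModel, list[ElementRecord]]:
    """Simulate a genome model and annotated elements with sequences.

    Element counts per compartment are Poisson with mean density x compartment
    size; midpoints are uniform within the compartment; lengths log-normal;
    sequences derive from a per-family consensus mutated for the element's
    age at ``config.rate`` under K2P.
    """
    rng = config.rng(_STREAM_GENOME)
    centromeres = _draw_centromeres(config, rng)
    model = GenomeModel(
        chrom_names=config.chrom_names,
        chrom_lengths=dict(zip(config.chrom_names, config.chrom_lengths)),
        bin_size=config.bin_size,
        true_centromeres=centromeres,
    )

    consensus: dict[str, str] = {}
    cen_consensus: dict[str, str] = {}
    for fam, fc in sorted(config.families.items()):
        if not fc.has_sequence:
            continue
        consensus[fam] = _random_sequence(fc.consensus_length, fc.gc_out, rng)
        if fc.cen_subfamily_divergence > 0:
            # centromere-specific subfamily: diverged and GC-shifted copy
            base = mutate_sequence(
                consensus[fam], fc.cen_subfamily_divergence, config.kappa, rng
            )
            n_swap = int(round((fc.gc_in - fc.gc_out) * len(base)))
            if n_swap > 0:
                codes = _encode(base)
                at_sites = np.flatnonzero((codes == 0) | (codes == 3))
                swap = rng.choice(at_sites, size=min(n_swap, len(at_sites)), replace=False)
                codes[swap] = rng.integers(1, 3, size=len(swap)).astype(np.int8)  # G or C
                base = _decode(codes)
            cen_consensus[fam] = base
        else:
            cen_consensus[fam] = consensus[fam]

    elements: list[ElementRecord] = []
    counter = 0
    for name in config.chrom_names:
        length = model.chrom_lengths[name]
        half = config.centromere_width // 2
        cen_lo = centromeres[name] - half + 1
        cen_hi = cen_lo + config.centromere_width - 1
        for fam, fc in sorted(config.families.items()):
            for inside in (True, False):
                span = config.centromere_width if inside else length - config.centromere_width
                dens = fc.density_in if inside else fc.density_out
                n = int(rng.poisson(dens * span / 1e6))
                if n == 0:
                    continue
                if inside:
                    mids = rng.integers(cen_lo, cen_hi + 1, size=n)
                else:
                    offs = rng.integers(1, span + 1, size=n)
                    mids = np.where(offs < cen_lo, offs, offs + config.centromere_width)
                med = fc.len_median_in if inside else fc.len_median_out
                lens = np.clip(
                    rng.lognormal(math.log(med), fc.len_sdlog, size=n), 50, None
                ).astype(int)
                age_med = fc.age_median_in if inside else fc.age_median_out
                ages = rng.lognormal(math.log(age_med), fc.age_sdlog, size=n)
                for m, ln, age in zip(mids, lens, ages):
                    counter += 1
                    start = max(1, int(m) - int(ln) // 2)
                    end = min(length, start + int(ln) - 1)
                    seq = None
                    if fc.has_sequence:
                        src = cen_consensus[fam] if inside else consensus[fam]
                        elen = end - start + 1
                        if elen > len(src):
                            reps = -(-elen // len(src))
                            src = src * reps
                        seq = mutate_sequence(
                            src[:elen], config.rate * age * 1e6, config.kappa, rng
                        )
                    elements.append(
                        ElementRecord(
                            chrom=name,
                            start=start,
                            end=end,
                            family=fam,
                            element_id=f"{fam}_{counter:05d}",
                            sequence=seq,
                            compartment="cen" if inside else "arm",
                            age_mya=float(age),
                        )
                    )
    elements.sort(key=lambda e: (e.chrom, e.start, e.element_id))
    return model, elements


# ---------------------------------------------------------------------------
# Hi-C simulation
# ---------------------------------------------------------------------------

def expected_cis(distance_bins: np.ndarray, config: SimConfig) -> np.ndarray:
    """Expected cis count at the given bin separations (power-law decay)."""
    d = np.asarray(distance_bins, dtype=float)
    out = np.empty_like(d)
    zero = d == 0
    out[~zero] = config.hic_cis_scale * d[~zero] ** (-config.hic_alpha)
    out[zero] = 2.0 * config.hic_cis_scale  # diagonal: self-ligation pile-up
    return out + config.hic_trans_background


def expected_trans(
    d_i: np.ndarray, d_j: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Expected trans count given bin distances to the two true centromeres."""
    di = np.asarray(d_i, dtype=float)[:, None]
    dj = np.asarray(d_j, dtype=float)[None, :]
    bump = config.hic_bump * np.exp(-(di**2 + dj**2) / (2.0 * config.hic_sigma**2))
    return config.hic_trans_background + bump


def simulate_hic(model: GenomeModel, config: SimConfig) -> ContactMap:
    """Poisson-sampled symmetric contact map with centromere trans bumps."""
    rng = config.rng(_STREAM_HIC)
    rows = []
    cen_bin: dict[str, int] = {}
    for name in model.chrom_names:
        nb = model.n_bins(name)
        for b in range(nb):
            rows.append((name, b * model.bin_size + 1))
        if model.true_centromeres is None:
            raise ValueError("model has no true centromeres to simulate around")
        cen_bin[name] = (model.true_centromeres[name] - 1) // model.bin_size
    bins = pd.DataFrame(rows, columns=["chrom", "start"])
    n = len(bins)
    expected = np.zeros((n, n))
    offsets = {}
    off = 0
    for name in model.chrom_names:
        nb = model.n_bins(name)
        offsets[name] = off
        idx = np.arange(nb)
        dist = np.abs(idx[:, None] - idx[None, :])
        expected[off : off + nb, off : off + nb] = expected_cis(dist, config)
        off += nb
    for i, a in enumerate(model.chrom_names):
        for b in model.chrom_names[i + 1 :]:
            na, nb_ = model.n_bins(a), model.n_bins(b)
            d_i = np.arange(na) - cen_bin[a]
            d_j = np.arange(nb_) - cen_bin[b]
            block = expected_trans(d_i, d_j, config)
            oa, ob = offsets[a], offsets[b]
            expected[oa : oa + na, ob : ob + nb_] = block
            expected[ob : ob + nb_, oa : oa + na] = block.T
    upper = np.triu(rng.poisson(expected))
    counts = upper + np.triu(upper, 1).T
    return ContactMap(bins, counts.astype(float), model.bin_size)


# ---------------------------------------------------------------------------
# LTR-RT locus simulation
# ---------------------------------------------------------------------------

_GAGPOL_DOMAINS = ("GAG", "PR", "RT", "RH", "INT")


#: Heterogeneous per-family (I, S, T) mix for demography demos: four families
#: at the genome-wide proportions and two solo-heavy families with expected
#: S:I = 5, i.e. above the high-death threshold of 3.
DEMO_FAMILY_MIX: tuple[tuple[float, float, float], ...] = (
    (0.13, 0.21, 0.66),
    (0.13, 0.21, 0.66),
    (0.13, 0.21, 0.66),
    (0.13, 0.21, 0.66),
    (0.10, 0.50, 0.40),
    (0.10, 0.50, 0.40),
)


def _family_mix(config: SimConfig) -> list[tuple[float, float, float]]:
    if config.ltr_family_mix is not None:
        mix = list(config.ltr_family_mix)
        if len(mix) != config.n_ltr_families:
            raise ValueError("ltr_family_mix length must equal n_ltr_families")
        return mix
    # every family follows the genome-wide proportions
    return [config.ist_proportions] * config.n_ltr_families


def simulate_ltr_loci(config: SimConfig) -> list[LTRLocus]:
    """Simulate LTR-RT loci with class evidence and age-diverged LTR pairs.

    Intact loci carry a complete ordered Gag-Pol domain hit set; truncated
    loci carry one qualifying one-sided partial hit; solo loci carry no hits
    and a single LTR. The 5' and 3' LTRs of paired loci are mutated
    independently for the locus age T at ``config.rate`` (so their expected
    K2P divergence is 2 r T).
    """
    rng = config.rng(_STREAM_LTR)
    mix = _family_mix(config)
    fam_consensus = []
    for _ in range(config.n_ltr_families):
        ln = int(np.clip(rng.lognormal(math.log(config.ltr_len_median),
                                       config.ltr_len_sdlog), 100, 3000))
        fam_consensus.append(_random_sequence(ln, 0.40, rng))

    loci: list[LTRLocus] = []
    n_scaffolds = max(4, config.n_ltr_loci // 25)
    scaffold_len = [
        config.short_scaffold_length
        if rng.random() < config.short_scaffold_fraction
        else config.long_scaffold_length
        for _ in range(n_scaffolds)
    ]
    for i in range(config.n_ltr_loci):
        fam = int(rng.integers(0, config.n_ltr_families))
        cls = ("I", "S", "T")[rng.choice(3, p=np.asarray(mix[fam]) / sum(mix[fam]))]
        if config.ltr_age_mya is not None:
            age = float(config.ltr_age_mya)
        else:
            age = float(rng.lognormal(math.log(config.ltr_age_median),
                                      config.ltr_age_sdlog))
        scf = int(rng.integers(0, n_scaffolds))
        ancestral = mutate_sequence(
            fam_consensus[fam], config.ltr_intra_family_divergence, config.kappa, rng
        )
        d_branch = config.rate * age * 1e6
        ltr5_seq = mutate_sequence(ancestral, d_branch, config.kappa, rng)
        paired = cls == "I"
        ltr3_seq = mutate_sequence(ancestral, d_branch, config.kappa, rng) if paired else None
        pos = int(rng.integers(1, scaffold_len[scf] - 20_000))
        L = len(ancestral)
        locus = LTRLocus(
            locus_id=f"ltr_{i + 1:05d}",
            chrom=f"scf{scf + 1:03d}",
            scaffold_length=scaffold_len[scf],
            ltr5=(pos, pos + L - 1),
            ltr3=(pos + L + 5000, pos + 2 * L + 4999) if paired else None,
            ltr5_seq=ltr5_seq,
            ltr3_seq=ltr3_seq,
            true_age_mya=age,
            cluster_id=None,
        )
        if cls == "I":
            locus.hits = (
                Hit("GagPol_ref", "internal", 1.0, 1e-50,
                    float(rng.uniform(60, 95)), _GAGPOL_DOMAINS),
            )
        elif cls == "T":
            locus.hits = (
                Hit(
                    "GagPol_ref",
                    "left" if rng.random() < 0.5 else "right",
                    float(rng.uniform(0.50, 0.95)),
                    float(10.0 ** -rng.uniform(9, 40)),
                    float(rng.uniform(31, 90)),
                    tuple(rng.permutation(_GAGPOL_DOMAINS)[:2]),
                ),
            )
        locus.class_label = cls  # generator ground truth; classifier re-derives
        if expected_pair_identity(age, config.rate, config.kappa) <= 0.80:
            warnings.warn(
                f"locus {locus.locus_id}: age {age:.2f} MYA implies expected LTR "
                "identity <= 80%, below the detection envelope",
                stacklevel=2,
            )
            locus.flagged = True
            locus.flag_reason = "expected_identity_below_80pct"
        loci.append(locus)
    return loci
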