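"""Readers and writers for the pipeline's plain-text interchange formats.

Internal coordinates are 1-based inclusive; the BED writer/reader converts
to/from 0-based half-open at the boundary. Tabular outputs start with
``# key=value`` comment headers that echo the seed and key parameters.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CentromerePointSet, CentromereRegion, ContactMap, ElementRecord, GenomeModel, Hit, LTRLocus, WindowTrack

__all__ = [
    "write_chrom_sizes", "read_chrom_sizes",
    "write_bed", "read_bed",
    "write_gff3", "read_gff3_elements",
    "write_fasta", "read_fasta",
    "write_contact_map", "read_contact_map",
    "write_calls", "read_calls",
    "write_regions", "read_regions",
    "write_bedgraph",
    "write_hits", "read_hits",
    "write_ltr_loci", "read_ltr_loci",
    "write_config_echo",
    "load_reference_karyotype",
]


def _header_lines(meta: dict | None) -> list[str]:
    return [f"# {k}={v}" for k, v in (meta or {}).items()]


def _write_tsv(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_chrom_sizes(path, model: GenomeModel, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        {"chrom": model.chrom_names,
         "length": [model.chrom_lengths[c] for c in model.chrom_names]}
    )
    _write_tsv(path, df, meta)


def read_chrom_sizes(path, bin_size: int = 100_000) -> GenomeModel:
    df = _read_tsv(path)
    return GenomeModel(
        chrom_names=tuple(df["chrom"]),
        chrom_lengths=dict(zip(df["chrom"], df["length"].astype(int))),
        bin_size=bin_size,
    )


def write_bed(path, elements: list[ElementRecord], meta: dict | None = None) -> None:
    """BED6; converts 1-based inclusive to 0-based half-open here only."""
    path = Path(path)
    with path.open("w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        for el in elements:
            fh.write(
                f"{el.chrom}\t{el.start - 1}\t{el.end}\t"
                f"{el.element_id}\t0\t{el.strand}\t{el.family}\n"
            )


def read_bed(path) -> list[ElementRecord]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append(
            ElementRecord(
                chrom=f[0],
                start=int(f[1]) + 1,
                end=int(f[2]),
                element_id=f[3] if len(f) > 3 else f"{f[0]}:{f[1]}",
                strand=f[5] if len(f) > 5 else "+",
                family=f[6] if len(f) > 6 else "NA",
            )
        )
    return out


def write_gff3(path, elements: list[ElementRecord], meta: dict | None = None,
               source: str = "centel") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for line in _header_lines(meta):
            fh.write(line + "\n")
        for el in elements:
            ftype = "gene" if el.family == "gene" else "dispersed_repeat"
            attrs = f"ID={el.element_id};family={el.family}"
            if el.compartment:
                attrs += f";compartment={el.compartment}"
            fh.write(
                f"{el.chrom}\t{source}\t{ftype}\t{el.start}\t{el.end}\t.\t"
                f"{el.strand}\t.\t{attrs}\n"
            )


def read_gff3_elements(path) -> list[ElementRecord]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        out.append(
            ElementRecord(
                chrom=f[0],
                start=int(f[3]),
                end=int(f[4]),
                family=attrs.get("family", f[2]),
                element_id=attrs.get("ID", f"{f[0]}:{f[3]}"),
                strand=f[6] if f[6] in "+-" else "+",
                compartment=attrs.get("compartment"),
            )
        )
    return out


def write_fasta(path, sequences: dict[str, str], seed: int | None = None) -> None:
    records = []
    for name, seq in sequences.items():
        desc = f"seed={seed}" if seed is not None else ""
        records.append(SeqRecord(Seq(seq), id=name, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_contact_map(coo_path, bins_path, cmap: ContactMap,
                      meta: dict | None = None) -> None:
    """Sparse upper-triangle COO TSV (bin_i <= bin_j) plus a bin index TSV."""
    iu, ju = np.triu_indices_from(cmap.counts)
    mask = cmap.counts[iu, ju] > 0
    coo = pd.DataFrame(
        {"bin_i": iu[mask], "bin_j": ju[mask],
         "count": cmap.counts[iu, ju][mask]}
    )
    _write_tsv(coo_path, coo, meta)
    bins = cmap.bins.reset_index().rename(columns={"index": "bin"})
    _write_tsv(bins_path, bins[["bin", "chrom", "start"]],
               {**(meta or {}), "bin_size": cmap.bin_size})


def read_contact_map(coo_path, bins_path) -> ContactMap:
    bins = _read_tsv(bins_path).sort_values("bin").reset_index(drop=True)
    bin_size = None
    for line in Path(bins_path).read_text().splitlines():
        if line.startswith("# bin_size="):
            bin_size = int(float(line.split("=", 1)[1]))
    if bin_size is None:
        starts = bins["start"].to_numpy()
        diffs = np.diff(starts)
        bin_size = int(diffs[diffs > 0].min())
    coo = _read_tsv(coo_path)
    n = len(bins)
    counts = np.zeros((n, n))
    i = coo["bin_i"].to_numpy(int)
    j = coo["bin_j"].to_numpy(int)
    counts[i, j] = coo["count"].to_numpy(float)
    counts[j, i] = coo["count"].to_numpy(float)
    return ContactMap(bins[["chrom", "start"]], counts, bin_size)


def write_calls(path, calls: CentromerePointSet, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {"chrom": c.chrom, "point_bp": c.point_bp, "bin": c.bin_index,
             "objective": c.objective_contribution}
            for c in calls.calls.values()
        ]
    )
    _write_tsv(path, df, {**(meta or {}), "objective": calls.objective,
                          "converged": calls.converged})


def read_calls(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_regions(path, rows: pd.DataFrame, meta: dict | None = None) -> None:
    _write_tsv(path, rows, meta)


def read_regions(path) -> list[CentromereRegion]:
    df = _read_tsv(path)
    return [
        CentromereRegion(chrom=r.chrom, start=int(r.start), end=int(r.end),
                         flagged=bool(getattr(r, "flagged", False)))
        for r in df.itertuples(index=False)
    ]


def write_bedgraph(path, tracks: dict[str, WindowTrack],
                   chrom_lengths: dict[str, int] | None = None,
                   meta: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        for chrom, track in tracks.items():
            W = track.window_size
            for w, val in enumerate(track.values):
                if np.isnan(val):
                    continue
                end = (w + 1) * W
                if chrom_lengths and chrom in chrom_lengths:
                    end = min(end, chrom_lengths[chrom])
                fh.write(f"{chrom}\t{w * W}\t{end}\t{val:g}\n")


def write_hits(path, loci: list[LTRLocus], meta: dict | None = None) -> None:
    rows = []
    for lc in loci:
        for h in lc.hits:
            rows.append(
                {"locus": lc.locus_id, "side": h.side, "target": h.target,
                 "coverage": h.coverage, "evalue": h.evalue,
                 "identity": h.identity, "domains": ",".join(h.domains)}
            )
    _write_tsv(path, pd.DataFrame(
        rows, columns=["locus", "side", "target", "coverage", "evalue",
                       "identity", "domains"]), meta)


def read_hits(path) -> dict[str, tuple[Hit, ...]]:
    df = _read_tsv(path)
    out: dict[str, list[Hit]] = {}
    for r in df.itertuples(index=False):
        domains = tuple(str(r.domains).split(",")) if pd.notna(r.domains) and r.domains else ()
        out.setdefault(r.locus, []).append(
            Hit(target=r.target, side=r.side, coverage=float(r.coverage),
                evalue=float(r.evalue), identity=float(r.identity),
                domains=domains)
        )
    return {k: tuple(v) for k, v in out.items()}


def write_ltr_loci(gff_path, fasta_path, hits_path, scaffolds_path,
                   loci: list[LTRLocus], meta: dict | None = None) -> None:
    """Locus GFF3 (LTR_retrotransposon + long_terminal_repeat features), LTR
    FASTA (paired records with /5 and /3 suffixes), hit TSV and scaffold
    sizes TSV."""
    with Path(gff_path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for line in _header_lines(meta):
            fh.write(line + "\n")
        for lc in loci:
            span_end = lc.ltr3[1] if lc.ltr3 else lc.ltr5[1]
            attrs = f"ID={lc.locus_id}"
            if lc.true_age_mya is not None:
                attrs += f";true_age_mya={lc.true_age_mya:.4f}"
            if lc.flagged:
                attrs += f";flag={lc.flag_reason}"
            fh.write(f"{lc.chrom}\tcentel\tLTR_retrotransposon\t{lc.ltr5[0]}\t"
                     f"{span_end}\t.\t+\t.\t{attrs}\n")
            fh.write(f"{lc.chrom}\tcentel\tlong_terminal_repeat\t{lc.ltr5[0]}\t"
                     f"{lc.ltr5[1]}\t.\t+\t.\tParent={lc.locus_id};side=5\n")
            if lc.ltr3:
                fh.write(f"{lc.chrom}\tcentel\tlong_terminal_repeat\t{lc.ltr3[0]}\t"
                         f"{lc.ltr3[1]}\t.\t+\t.\tParent={lc.locus_id};side=3\n")
    seqs = {}
    for lc in loci:
        if lc.ltr5_seq:
            seqs[f"{lc.locus_id}/5"] = lc.ltr5_seq
        if lc.ltr3_seq:
            seqs[f"{lc.locus_id}/3"] = lc.ltr3_seq
    write_fasta(fasta_path, seqs, seed=(meta or {}).get("seed"))
    write_hits(hits_path, loci, meta)
    scaffolds = {}
    for lc in loci:
        scaffolds[lc.chrom] = lc.scaffold_length
    _write_tsv(scaffolds_path,
               pd.DataFrame(sorted(scaffolds.items()), columns=["chrom", "length"]),
               meta)


def read_ltr_loci(gff_path, fasta_path, hits_path, scaffolds_path) -> list[LTRLocus]:
    seqs = read_fasta(fasta_path)
    hits = read_hits(hits_path)
    scaffolds = dict(
        _read_tsv(scaffolds_path)[["chrom", "length"]].itertuples(index=False)
    )
    loci: dict[str, LTRLocus] = {}
    ltr_sides: dict[str, dict[str, tuple[int, int]]] = {}
    for line in Path(gff_path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        if f[2] == "LTR_retrotransposon":
            lid = attrs["ID"]
            loci[lid] = LTRLocus(
                locus_id=lid,
                chrom=f[0],
                scaffold_length=int(scaffolds[f[0]]),
                ltr5=(int(f[3]), int(f[4])),  # placeholder until sides parsed
                hits=hits.get(lid, ()),
                true_age_mya=float(attrs["true_age_mya"]) if "true_age_mya" in attrs else None,
                flagged="flag" in attrs,
                flag_reason=attrs.get("flag"),
            )
        elif f[2] == "long_terminal_repeat":
            ltr_sides.setdefault(attrs["Parent"], {})[attrs["side"]] = (
                int(f[3]), int(f[4])
            )
    for lid, lc in loci.items():
        sides = ltr_sides.get(lid, {})
        if "5" in sides:
            lc.ltr5 = sides["5"]
        lc.ltr3 = sides.get("3")
        lc.ltr5_seq = seqs.get(f"{lid}/5")
        lc.ltr3_seq = seqs.get(f"{lid}/3")
    return [loci[k] for k in sorted(loci)]


def write_config_echo(path, params: dict) -> None:
    """key = value echo of every parameter, seed included."""
    with Path(path).open("w") as fh:
        for k, v in params.items():
            fh.write(f"{k} = {v}\n")


def load_reference_karyotype() -> pd.DataFrame:
    """Published yellowhorn 'JGXP' centromere/karyotype table (15 chromosomes):
    predicted Hi-C point, refined region, size, arm ratio and term."""
    path = Path(__file__).parent / "data" / "yellowhorn_centromeres.tsv"
    return pd.read_csv(path, sep="\t", comment="#")
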