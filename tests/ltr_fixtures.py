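"""Hand-built LTR-RT loci spanning every I/S/T threshold boundary."""

from centel.core import Hit, LTRLocus

ALL_DOMAINS = ("GAG", "PR", "RT", "RH", "INT")


def _locus(lid, hits=(), scaffold_length=10_000_000, **kw):
    return LTRLocus(locus_id=lid, chrom="scf1", scaffold_length=scaffold_length,
                    ltr5=(100, 600), hits=tuple(hits), **kw)


def boundary_fixture():
    """12 loci: expected classes under the rules 'intact iff complete ordered
    Gag-Pol', 'truncated iff a one-sided hit with coverage >= 0.50, E < 1e-8,
    identity > 30%', 'solo otherwise'."""
    return [
        # intact: complete ordered Gag-Pol
        (_locus("L01", [Hit("gp", "internal", 1.0, 1e-50, 80, ALL_DOMAINS)]), "I"),
        # intact: domains split across two internal hits, still in order
        (_locus("L02", [Hit("gp", "internal", 0.6, 1e-30, 70, ("GAG", "PR", "RT")),
                        Hit("gp", "internal", 0.4, 1e-20, 70, ("RH", "INT"))]), "I"),
        # internal but incomplete -> solo
        (_locus("L03", [Hit("gp", "internal", 1.0, 1e-50, 80,
                            ("GAG", "PR", "RT", "RH"))]), "S"),
        # internal complete set but out of order -> not intact -> solo
        (_locus("L04", [Hit("gp", "internal", 1.0, 1e-50, 80,
                            ("INT", "RH", "RT", "PR", "GAG"))]), "S"),
        # truncated thresholds: coverage exactly 0.50 passes ("at least 50%")
        (_locus("L05", [Hit("gp", "left", 0.50, 1e-9, 31.0)]), "T"),
        # coverage 0.49 fails
        (_locus("L06", [Hit("gp", "left", 0.49, 1e-9, 90.0)]), "S"),
        # e-value exactly 1e-8 fails (strict <)
        (_locus("L07", [Hit("gp", "right", 0.60, 1e-8, 90.0)]), "S"),
        # e-value 1e-9 passes
        (_locus("L08", [Hit("gp", "right", 0.60, 1e-9, 90.0)]), "T"),
        # identity exactly 30 fails (strict >)
        (_locus("L09", [Hit("gp", "right", 0.60, 1e-9, 30.0)]), "S"),
        # identity 31 passes
        (_locus("L10", [Hit("gp", "left", 0.60, 1e-12, 45.0)]), "T"),
        # no evidence at all -> solo
        (_locus("L11"), "S"),
        # one qualifying among several failing side hits
        (_locus("L12", [Hit("gp", "left", 0.40, 1e-9, 90.0),
                        Hit("gp", "right", 0.70, 1e-10, 50.0)]), "T"),
    ]
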