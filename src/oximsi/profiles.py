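"""Reference planted-truth profiles for the bundled demo screens.

Two synthetic screens mirror the study conditions of the assay's
validation experiments:

* ``TAT1``: 20 proteinogenic amino donors against alpha-ketoglutarate;
  six donors (Tyr, His, Leu, Met, Phe, Trp) are active.
* ``TAR1``: 31 amino donors against three keto acceptors
  (alpha-ketoglutarate, pyruvate, phenylpyruvate); 13 donors are active
  with at least one acceptor and all three acceptors are used.  Four
  additional donors are planted just below the 0.1 ratio threshold
  (between 0.05 and 0.1) to exercise threshold-sensitivity analysis.

Values are *observed* fractional-conversion ratios; they are converted
to true converted fractions through the assay stoichiometry (10 mM
donor, 6 mM acceptor) when building a :class:`~oximsi.simulate.TruthProfile`.
"""

from __future__ import annotations

from .simulate import TruthProfile

__all__ = [
    "PROTEINOGENIC_DONORS",
    "SCREEN_DONORS_31",
    "SCREEN_ACCEPTORS",
    "TAT1_RATIOS",
    "TAR1_RATIOS",
    "TAT1_ACTIVE_DONORS",
    "TAR1_ACTIVE_DONORS",
    "TAR1_BORDERLINE_DONORS",
    "truth_from_observed_ratios",
]

PROTEINOGENIC_DONORS = [
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
]

SCREEN_DONORS_31 = [
    "5-HT", "5-HTP", "AABA", "Ala", "Arg", "Asn", "Asp", "BABA", "Cys",
    "DA", "DOPA", "GABA", "Gln", "Glu", "Gly", "His", "Ile", "Leu", "Lys",
    "Met", "O-MTY", "Phe", "Pro", "SAM", "Ser", "Thr", "Trp", "Tym",
    "Tyr", "Val", "beta-Ala",
]

SCREEN_ACCEPTORS = ["alpha-KG", "pyruvate", "phenylpyruvate"]

#: observed conversion ratios planted for the 20-donor tyrosine-AT screen
TAT1_RATIOS: dict[tuple[str, str], float] = {
    ("Tyr", "alpha-KG"): 0.85,
    ("Phe", "alpha-KG"): 0.65,
    ("Trp", "alpha-KG"): 0.60,
    ("Leu", "alpha-KG"): 0.55,
    ("Met", "alpha-KG"): 0.45,
    ("His", "alpha-KG"): 0.35,
}

TAT1_ACTIVE_DONORS = sorted({d for d, _ in TAT1_RATIOS})

#: observed conversion ratios planted for the 31-donor x 3-acceptor screen.
#: Glu/alpha-KG is planted active but is a degenerate pair (its product IS
#: the acceptor), so the pipeline must recover Glu via the other acceptors.
TAR1_RATIOS: dict[tuple[str, str], float] = {
    # alpha-ketoglutarate
    ("Trp", "alpha-KG"): 0.80, ("Tyr", "alpha-KG"): 0.60,
    ("Phe", "alpha-KG"): 0.60, ("Leu", "alpha-KG"): 0.50,
    ("Met", "alpha-KG"): 0.45, ("His", "alpha-KG"): 0.40,
    ("Ala", "alpha-KG"): 0.35, ("AABA", "alpha-KG"): 0.35,
    ("Asp", "alpha-KG"): 0.30, ("Asn", "alpha-KG"): 0.30,
    ("O-MTY", "alpha-KG"): 0.30, ("Arg", "alpha-KG"): 0.25,
    ("Glu", "alpha-KG"): 0.50,  # degenerate pair, not evaluable
    # pyruvate
    ("Trp", "pyruvate"): 0.70, ("Glu", "pyruvate"): 0.50,
    ("Tyr", "pyruvate"): 0.55, ("Phe", "pyruvate"): 0.50,
    ("Leu", "pyruvate"): 0.45, ("Met", "pyruvate"): 0.40,
    ("His", "pyruvate"): 0.35, ("AABA", "pyruvate"): 0.30,
    ("Asn", "pyruvate"): 0.25, ("O-MTY", "pyruvate"): 0.25,
    ("Arg", "pyruvate"): 0.20,
    # phenylpyruvate (weaker overall preference)
    ("Trp", "phenylpyruvate"): 0.40, ("Glu", "phenylpyruvate"): 0.35,
    ("Ala", "phenylpyruvate"): 0.30, ("Tyr", "phenylpyruvate"): 0.30,
    ("Leu", "phenylpyruvate"): 0.25, ("Met", "phenylpyruvate"): 0.20,
    ("His", "phenylpyruvate"): 0.20, ("AABA", "phenylpyruvate"): 0.20,
    ("Asn", "phenylpyruvate"): 0.15, ("Arg", "phenylpyruvate"): 0.15,
    ("O-MTY", "phenylpyruvate"): 0.15,
    # borderline: below 0.1, above 0.05 (visible only at a lowered threshold)
    ("Gln", "alpha-KG"): 0.07, ("Ile", "alpha-KG"): 0.08,
    ("Val", "pyruvate"): 0.07, ("Ser", "pyruvate"): 0.06,
}

TAR1_ACTIVE_DONORS = sorted(
    {d for (d, a), r in TAR1_RATIOS.items() if r > 0.1 and not (d == "Glu" and a == "alpha-KG")}
)
TAR1_BORDERLINE_DONORS = sorted({d for (d, a), r in TAR1_RATIOS.items() if 0.05 < r <= 0.1})


def truth_from_observed_ratios(
    enzyme: str,
    ratios: dict[tuple[str, str], float],
    donor_mM: float = 10.0,
    acceptor_mM: float = 6.0,
) -> TruthProfile:
    """Build a :class:`TruthProfile` planting given observed conversion ratios."""
    truth = TruthProfile(donor_mM=donor_mM, acceptor_mM=acceptor_mM)
    for (donor, acceptor), r in ratios.items():
        truth.conversion[(enzyme, donor, acceptor)] = truth.for_observed_ratio(r)
    return truth
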