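"""Published stopped-flow rate constants for human Brr2 constructs.

Rate constants of mant-ADP / mant-ATPgS association (k1, uM^-1 s^-1) and
dissociation (k_minus1, s^-1) for each helicase cassette, measured by
FRET-based pre-steady-state kinetics on the isolated cassettes
(hBrr2-NC, residues 395-1324; hBrr2-CC, residues 1282-2136), the
full-length enzyme (hBrr2-FL), the N-terminally truncated hBrr2-T1, and
interface / linker / pocket mutants of hBrr2-T1.  These serve as
generating truths for the synthetic-data module and as calibration for
phase assignment.

Each entry: (k1, k1_se, k_minus1, k_minus1_se).
"""

from __future__ import annotations

from .model import BindingScheme, BindingSite

__all__ = [
    "RATE_CONSTANTS",
    "AFFINITIES",
    "NC_CC_BOUNDARY",
    "binding_scheme",
    "published_affinity_frame",
]

# residue number at which the C-terminal cassette construct begins;
# used as the default NC/CC partition boundary
NC_CC_BOUNDARY = 1282

#: (construct, nucleotide, cassette) -> (k1, k1_se, k_minus1, k_minus1_se)
RATE_CONSTANTS: dict[tuple[str, str, str], tuple[float, float, float, float]] = {
    # isolated cassettes (single-exponential fits)
    ("hBrr2-NC", "mant-ADP", "NC"): (1.0, 0.1, 1.9, 0.1),
    ("hBrr2-NC", "mant-ATPgS", "NC"): (0.3, 0.02, 1.6, 0.02),
    ("hBrr2-CC", "mant-ADP", "CC"): (0.5, 0.01, 2.0e-3, 0.2e-3),
    ("hBrr2-CC", "mant-ATPgS", "CC"): (0.1, 0.001, 2.0e-3, 0.2e-3),
    # dual-cassette constructs (double-exponential fits)
    ("hBrr2-FL", "mant-ADP", "NC"): (2.8, 0.03, 1.5, 0.02),
    ("hBrr2-FL", "mant-ADP", "CC"): (0.4, 0.01, 1.0e-3, 0.1e-3),
    ("hBrr2-FL", "mant-ATPgS", "NC"): (1.0, 0.02, 1.5, 0.04),
    ("hBrr2-FL", "mant-ATPgS", "CC"): (0.1, 0.01, 1.0e-3, 0.1e-3),
    ("hBrr2-T1", "mant-ADP", "NC"): (2.5, 0.1, 1.3, 0.02),
    ("hBrr2-T1", "mant-ADP", "CC"): (0.4, 0.02, 1.0e-3, 0.1e-3),
    ("hBrr2-T1", "mant-ATPgS", "NC"): (2.5, 0.03, 1.2, 0.04),
    ("hBrr2-T1", "mant-ATPgS", "CC"): (0.1, 0.01, 0.9e-3, 0.01e-3),
    # hBrr2-T1 mutants
    ("R603A", "mant-ADP", "NC"): (0.2, 0.03, 1.4, 0.04),
    ("R603A", "mant-ADP", "CC"): (0.02, 0.001, 1.0e-3, 0.1e-3),
    ("R603A", "mant-ATPgS", "NC"): (0.3, 0.03, 1.0, 0.04),
    ("R603A", "mant-ATPgS", "CC"): (0.02, 0.001, 1.0e-3, 0.2e-3),
    ("R637A", "mant-ADP", "NC"): (3.4, 0.2, 1.2, 0.03),
    ("R637A", "mant-ADP", "CC"): (0.5, 0.01, 1.0e-3, 0.1e-3),
    ("R637A", "mant-ATPgS", "NC"): (0.4, 0.04, 1.0, 0.1),
    ("R637A", "mant-ATPgS", "CC"): (0.02, 0.001, 1.0e-3, 0.04e-3),
    ("S1087L", "mant-ADP", "NC"): (2.7, 0.1, 1.4, 0.04),
    ("S1087L", "mant-ADP", "CC"): (0.5, 0.01, 1.0e-3, 0.03e-3),
    ("S1087L", "mant-ATPgS", "NC"): (2.2, 0.21, 1.4, 0.04),
    ("S1087L", "mant-ATPgS", "CC"): (0.1, 0.004, 1.0e-3, 0.4e-3),
    ("PPP1296-8AAA", "mant-ADP", "NC"): (2.9, 0.1, 2.2, 0.1),
    ("PPP1296-8AAA", "mant-ADP", "CC"): (0.52, 0.003, 2.0e-3, 0.04e-3),
    ("PPP1296-8AAA", "mant-ATPgS", "NC"): (0.5, 0.03, 2.2, 0.1),
    ("PPP1296-8AAA", "mant-ATPgS", "CC"): (0.03, 0.002, 2.0e-3, 0.4e-3),
    ("GK1355-6QE", "mant-ADP", "NC"): (1.3, 0.1, 1.5, 0.02),
    ("GK1355-6QE", "mant-ATPgS", "NC"): (0.4, 0.02, 1.7, 0.1),
    ("H1548A", "mant-ADP", "NC"): (3.3, 0.3, 1.2, 0.1),
    ("H1548A", "mant-ADP", "CC"): (0.5, 0.01, 1.0e-3, 0.3e-3),
    ("H1548A", "mant-ATPgS", "NC"): (0.2, 0.02, 1.3, 0.1),
    ("H1548A", "mant-ATPgS", "CC"): (0.02, 0.001, 1.0e-3, 0.03e-3),
}

#: published equilibrium Kd values, (construct, nucleotide, cassette) -> (Kd uM, se uM)
AFFINITIES: dict[tuple[str, str, str], tuple[float, float]] = {
    ("hBrr2-NC", "mant-ADP", "NC"): (2.0, 0.2),
    ("hBrr2-NC", "mant-ATPgS", "NC"): (5.8, 0.4),
    ("hBrr2-CC", "mant-ADP", "CC"): (4e-3, 0.4e-3),
    ("hBrr2-CC", "mant-ATPgS", "CC"): (30e-3, 3e-3),
    ("hBrr2-FL", "mant-ADP", "NC"): (0.5, 0.01),
    ("hBrr2-FL", "mant-ADP", "CC"): (2e-3, 0.2e-3),
    ("hBrr2-FL", "mant-ATPgS", "NC"): (1.6, 0.1),
    ("hBrr2-FL", "mant-ATPgS", "CC"): (10e-3, 1e-3),
    ("hBrr2-T1", "mant-ADP", "NC"): (0.5, 0.02),
    ("hBrr2-T1", "mant-ADP", "CC"): (2e-3, 0.3e-3),
    ("hBrr2-T1", "mant-ATPgS", "NC"): (0.5, 0.02),
    ("hBrr2-T1", "mant-ATPgS", "CC"): (10e-3, 1e-3),
}

#: default protein concentrations used in the stopped-flow experiments (uM)
PROTEIN_CONC: dict[str, float] = {
    "hBrr2-NC": 0.4,
    "hBrr2-CC": 0.2,
}

# relative phase amplitudes: the CC pocket has two nearby tryptophan FRET
# donors versus one at the NC, motivating a somewhat larger CC amplitude
DEFAULT_AMPLITUDES = {"NC": 0.45, "CC": 0.55}


def published_affinity_frame():
    """Published Kd values as an affinity table (for fold-ratio arithmetic).

    The printed Kd values were computed from unrounded rate constants, so
    they are the authoritative source for affinity folds; recomputing
    Kd = k_minus1/k1 from the rounded printed rates gives slightly
    different numbers for some entries.
    """
    import pandas as pd

    rows = []
    for (con, nuc, cas), (kd, kd_se) in AFFINITIES.items():
        km1 = RATE_CONSTANTS[(con, nuc, cas)][2]
        rows.append(
            {
                "construct": con,
                "nucleotide": nuc,
                "cassette": cas,
                "k1": RATE_CONSTANTS[(con, nuc, cas)][0],
                "k_minus1": km1,
                "kd_uM": kd,
                "kd_se_uM": kd_se,
                "provenance": "published",
            }
        )
    return pd.DataFrame(rows)


def binding_scheme(
    construct: str,
    nucleotide: str,
    protein_conc: float | None = None,
    baseline: float = 2.0,
    amplitudes: dict[str, float] | None = None,
) -> BindingScheme:
    """Build a :class:`BindingScheme` from the published rate constants.

    Single-cassette constructs yield one site (amplitude 1), dual-cassette
    constructs two sites with the default NC/CC amplitude split.
    """
    cassettes = [
        cas
        for (con, nuc, cas) in RATE_CONSTANTS
        if con == construct and nuc == nucleotide
    ]
    if not cassettes:
        raise KeyError(f"no rate constants for {construct!r} / {nucleotide!r}")
    amplitudes = amplitudes or (
        {cassettes[0]: 1.0} if len(cassettes) == 1 else dict(DEFAULT_AMPLITUDES)
    )
    sites = []
    for cas in sorted(cassettes):  # CC, NC -> stable order; labels carry identity
        k1, _, km1, _ = RATE_CONSTANTS[(construct, nucleotide, cas)]
        sites.append(BindingSite(cas, k1, km1, amplitudes[cas]))
    if protein_conc is None:
        protein_conc = PROTEIN_CONC.get(construct, 0.2)
    return BindingScheme(tuple(sites), protein_conc, baseline)
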