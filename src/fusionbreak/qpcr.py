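"""Breakpoint-specific qPCR: standard-curve statistics and reverse-primer design.

The MRD assay couples a fixed forward primer and dual-labeled probe 5' of
the breakpoint cluster with a patient-specific reverse primer 3' of the
junction. Standard curves are tenfold dilution series; efficiency follows
the usual 10^(-1/slope) - 1 relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from Bio.SeqUtils import MeltingTemp as mt

from .assay import Primer, revcomp

__all__ = [
    "StandardCurvePoint",
    "CurveFit",
    "PrimerConstraints",
    "PrimerCandidate",
    "TCF3_QF",
    "TCF3_FAM_PROBE",
    "fit_standard_curve",
    "efficiency_from_slope",
    "successive_delta_ct",
    "design_reverse_primer",
    "melting_temperature",
    "load_reference_curve_table",
]

#: Fixed assay components (5'->3'). The probe is dual-labeled 6FAM/BHQ1 in
#: the wet-lab assay; only the annealing sequence matters in silico.
TCF3_QF = Primer("TCF3-qF", "CAGGCAGACTTTCCAAGTACCTT")
TCF3_FAM_PROBE = "CTATCACTCCTAGGCCAGGGCATCT"


@dataclass(frozen=True)
class StandardCurvePoint:
    log10_concentration: float
    ct: float

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError("ct must be > 0")


@dataclass(frozen=True)
class CurveFit:
    slope: float
    intercept: float
    r_squared: float
    efficiency: float


def fit_standard_curve(points: Sequence[StandardCurvePoint]) -> CurveFit:
    """Ordinary least squares of Ct on log10 concentration.

    ``r_squared`` is the squared Pearson correlation of the fit. Requires at
    least two points at two distinct concentrations.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 standard-curve points")
    x = np.array([p.log10_concentration for p in points], dtype=float)
    y = np.array([p.ct for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("all concentrations equal; cannot fit a curve")
    res = stats.linregress(x, y)
    r2 = 1.0 if len(points) == 2 else float(res.rvalue) ** 2
    slope = float(res.slope)
    return CurveFit(
        slope=slope,
        intercept=float(res.intercept),
        r_squared=r2,
        # a non-negative slope is not a usable dilution curve
        efficiency=efficiency_from_slope(slope) if slope < 0 else float("nan"),
    )


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency 10^(-1/slope) - 1 (1.0 = perfect doubling)."""
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    return 10.0 ** (-1.0 / slope) - 1.0


def successive_delta_ct(cts: Sequence[float]) -> list[float]:
    """Ct differences between successive dilutions (ordered by decreasing
    concentration)."""
    if len(cts) < 2:
        raise ValueError("need at least 2 Ct values")
    return [round(b - a, 10) for a, b in zip(cts, cts[1:])]


@dataclass(frozen=True)
class PrimerConstraints:
    min_len: int = 18
    max_len: int = 30
    tm_min: float = 58.0
    tm_max: float = 62.0
    max_amplicon: int = 300
    tm_method: str = "nearest-neighbor"


@dataclass(frozen=True)
class PrimerCandidate:
    primer: Primer
    binding_start: int   # 1-based on the fusion sequence (plus strand)
    binding_end: int
    amplicon_len: int
    tm: float


def melting_temperature(seq: str,
                        method: Literal["wallace", "nearest-neighbor"] = "nearest-neighbor",
                        ) -> float:
    """Oligo melting temperature in degrees Celsius.

    wallace: 2(A+T) + 4(G+C). nearest-neighbor: unified thermodynamic
    parameters (SantaLucia 2004 table as shipped with Biopython) at 50 mM
    Na+ and 250 nM primer.
    """
    s = seq.upper()
    if not s or any(c not in "ACGT" for c in s):
        raise ValueError("sequence must be a non-empty A/C/G/T string")
    if method == "wallace":
        return float(2 * (s.count("A") + s.count("T")) + 4 * (s.count("G") + s.count("C")))
    if method == "nearest-neighbor":
        return float(mt.Tm_NN(s, Na=50, dnac1=250, dnac2=0, saltcorr=5))
    raise ValueError(f"unknown method {method!r}")


def design_reverse_primer(fusion_seq: str, junction_pos: int, donor_ref: str,
                          acceptor_ref: str,
                          constraints: PrimerConstraints = PrimerConstraints(),
                          forward: Primer = TCF3_QF, probe: str = TCF3_FAM_PROBE,
                          ) -> tuple[list[PrimerCandidate], dict[str, int]]:
    """Enumerate patient-specific reverse primers 3' of a fusion junction.

    Candidates are reverse complements of plus-strand windows lying entirely
    3' of ``junction_pos`` (1-based, last donor-derived base). A candidate
    must satisfy the length/Tm/amplicon constraints and must not have an
    exact-match binding site on either strand of the donor reference, which
    would permit junction-independent amplification with the fixed forward
    primer. (Binding the acceptor reference is inherent to the design - the
    reverse primer is acceptor-intron sequence - and is not penalized.)

    Returns candidates ranked by closeness of Tm to the window midpoint,
    then amplicon length, plus a per-constraint failure tally.
    """
    fusion = fusion_seq.upper()
    if not 1 <= junction_pos <= len(fusion):
        raise ValueError("junction_pos outside fusion sequence")
    fwd_idx = fusion.find(forward.sequence)
    probe_idx = fusion.find(probe.upper())
    if fwd_idx < 0 or probe_idx < 0:
        raise ValueError("fusion sequence must contain the forward primer and probe")
    if fwd_idx + len(forward) - 1 >= junction_pos or probe_idx + len(probe) - 1 >= junction_pos:
        raise ValueError("forward primer and probe must lie 5' of the junction")

    donor = donor_ref.upper()
    donor_rc = revcomp(donor)
    tm_mid = (constraints.tm_min + constraints.tm_max) / 2
    fails = {"tm": 0, "amplicon": 0, "specificity": 0}
    candidates: list[PrimerCandidate] = []
    for start in range(junction_pos + 1, len(fusion) + 1):
        for length in range(constraints.min_len, constraints.max_len + 1):
            end = start + length - 1
            if end > len(fusion):
                break
            window = fusion[start - 1:end]
            amplicon = end - (fwd_idx + 1) + 1
            if amplicon > constraints.max_amplicon:
                fails["amplicon"] += 1
                continue
            tm = melting_temperature(window, "nearest-neighbor"
                                     if constraints.tm_method == "nearest-neighbor" else "wallace")
            if not constraints.tm_min <= tm <= constraints.tm_max:
                fails["tm"] += 1
                continue
            primer_seq = revcomp(window)
            if primer_seq in donor or primer_seq in donor_rc:
                fails["specificity"] += 1
                continue
            if acceptor_ref and acceptor_ref.upper().count(window) > 1:
                fails["specificity"] += 1  # multi-site priming in the acceptor intron
                continue
            candidates.append(PrimerCandidate(
                primer=Primer(f"rev_{start}_{length}", primer_seq),
                binding_start=start, binding_end=end,
                amplicon_len=amplicon, tm=tm))
    candidates.sort(key=lambda c: (abs(c.tm - tm_mid), c.amplicon_len))
    return candidates, fails


def load_reference_curve_table() -> pd.DataFrame:
    """Published per-patient standard-curve statistics (delta-Ct, slope, R2,
    efficiency) shipped as a CSV fixture."""
    ref = resources.files("fusionbreak.data").joinpath("qpcr_table2.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
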