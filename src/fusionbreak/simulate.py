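"""Synthetic fusion genomes with known truth, for round-trip testing.

Generates random reference introns, then derivative chromosomes whose
breakpoints follow the empirical cluster mixture (a tight donor hotspot
holding ~83% of events; two acceptor clusters holding ~37% and ~51%) and
whose junctions follow a nonhomologous end-joining profile: mostly zero
microhomology, frequent short non-template insertions, rare inverted
segments and foreign-sequence inserts.

Microhomology is planted honestly: for a requested homology of k bases the
generator searches the sampled acceptor cluster for junction sites whose
upstream context genuinely matches the donor suffix (and mismatches at
position k+1), so the derivative is a plain two-part concatenation and the
junction caller must rediscover the homology from sequence alone.

All randomness flows from one seeded numpy Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clusters import Region

__all__ = [
    "BreakpointModel",
    "JunctionModel",
    "TruthRecord",
    "FusionEvent",
    "Cohort",
    "generate_reference",
    "simulate_fusion",
    "simulate_cohort",
]

_BASES = np.array(["A", "C", "G", "T"])

#: Empirical mixture weights (printed cohort fractions, not fitted values).
TCF3_HOTSPOT_WEIGHT = 0.83
PBX1_CLUSTER_WEIGHTS = (0.37, 0.51)

# Full-length cluster bounds; the scaled model rescales these proportionally.
_FULL_PBX1_LEN = 229_182
_FULL_CLUSTERS = (Region(220_000, 229_182, "cluster1"), Region(119_000, 155_100, "cluster2"))
_TCF3_LEN = 3_289
_TCF3_HOTSPOT = Region(1_151, 1_190, "hotspot")


class SimulationError(RuntimeError):
    """Raised when a junction satisfying the sampled parameters cannot be placed."""


@dataclass(frozen=True)
class BreakpointModel:
    """Mixture model over breakpoint positions, one hotspot side and one
    multi-cluster side."""

    tcf3_length: int
    pbx1_length: int
    tcf3_hotspot: Region = _TCF3_HOTSPOT
    tcf3_hotspot_weight: float = TCF3_HOTSPOT_WEIGHT
    pbx1_clusters: tuple[Region, ...] = _FULL_CLUSTERS
    pbx1_cluster_weights: tuple[float, ...] = PBX1_CLUSTER_WEIGHTS

    def __post_init__(self) -> None:
        if not 0 <= self.tcf3_hotspot_weight <= 1:
            raise ValueError("hotspot weight outside [0,1]")
        if len(self.pbx1_clusters) != len(self.pbx1_cluster_weights):
            raise ValueError("cluster/weight length mismatch")
        if sum(self.pbx1_cluster_weights) > 1 + 1e-9:
            raise ValueError("cluster weights exceed 1")

    @property
    def tcf3_background_weight(self) -> float:
        return 1.0 - self.tcf3_hotspot_weight

    @property
    def pbx1_background_weight(self) -> float:
        return 1.0 - sum(self.pbx1_cluster_weights)

    @classmethod
    def scaled(cls, pbx1_length: int = 20_000, tcf3_length: int = _TCF3_LEN) -> "BreakpointModel":
        """Desk-scale model: the long acceptor intron shrunk proportionally
        (default 229,182 -> 20,000, ~1:11.5) with cluster bounds rescaled."""
        s = pbx1_length / _FULL_PBX1_LEN
        clusters = tuple(
            Region(max(1, round(r.start * s)), min(pbx1_length, round(r.end * s)), r.label)
            for r in _FULL_CLUSTERS)
        return cls(tcf3_length=tcf3_length, pbx1_length=pbx1_length, pbx1_clusters=clusters)

    @classmethod
    def full(cls) -> "BreakpointModel":
        return cls(tcf3_length=_TCF3_LEN, pbx1_length=_FULL_PBX1_LEN)


@dataclass(frozen=True)
class JunctionModel:
    """NHEJ-style junction feature model.

    ``mh_probs`` is a categorical over microhomology lengths (the source
    cohort is only described qualitatively as "mostly none", so the default
    is a documented assumption). Insertions are mutually exclusive with
    microhomology > 0: a zero-homology event gains a non-template insert
    with probability ``p_insert``, its length 1 + Geometric(``insert_geom_p``).
    """

    mh_probs: tuple[tuple[int, float], ...] = ((0, 0.70), (1, 0.15), (2, 0.10), (3, 0.05))
    p_insert: float = 0.5
    insert_geom_p: float = 0.35
    p_inversion: float = 0.0
    p_foreign: float = 0.0
    inversion_len: int = 788
    foreign_insert_len: int = 100

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.mh_probs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mh_probs must sum to 1")
        for p in (self.p_insert, self.p_inversion, self.p_foreign):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0,1]")


@dataclass(frozen=True)
class TruthRecord:
    event_id: str
    tcf3_break: int        # last donor base on the derivative (1-based)
    pbx1_break: int        # first acceptor base on the derivative (1-based)
    microhomology_len: int
    inserted_seq: str
    insert_class: str
    reciprocal: bool


@dataclass(frozen=True)
class FusionEvent:
    der19: str
    der1: str | None
    truth: TruthRecord


@dataclass(frozen=True)
class Cohort:
    tcf3_ref: str
    pbx1_ref: str
    foreign_db: tuple[str, ...]
    events: tuple[FusionEvent, ...]

    def truth_table(self) -> pd.DataFrame:
        rows = [{
            "event_id": e.truth.event_id,
            "tcf3_break": e.truth.tcf3_break,
            "pbx1_break": e.truth.pbx1_break,
            "microhomology_len": e.truth.microhomology_len,
            "inserted_seq": e.truth.inserted_seq,
            "insert_class": e.truth.insert_class,
            "reciprocal": e.truth.reciprocal,
        } for e in self.events]
        return pd.DataFrame(rows, columns=[
            "event_id", "tcf3_break", "pbx1_break", "microhomology_len",
            "inserted_seq", "insert_class", "reciprocal"])

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write references, derivatives (FASTA) and the truth table (TSV)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "references": outdir / "references.fa",
            "derivatives": outdir / "derivatives.fa",
            "truth": outdir / "truth.tsv",
        }
        with open(paths["references"], "w") as fh:
            _write_fasta_record(fh, "TCF3_intron_synthetic", self.tcf3_ref)
            _write_fasta_record(fh, "PBX1_intron_synthetic", self.pbx1_ref)
            for i, f in enumerate(self.foreign_db):
                _write_fasta_record(fh, f"foreign_{i}", f)
        with open(paths["derivatives"], "w") as fh:
            for e in self.events:
                _write_fasta_record(fh, f"{e.truth.event_id}_der19", e.der19)
                if e.der1 is not None:
                    _write_fasta_record(fh, f"{e.truth.event_id}_der1", e.der1)
        self.truth_table().to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _write_fasta_record(fh, name: str, seq: str, width: int = 70) -> None:
    fh.write(f">{name}\n")
    for i in range(0, len(seq), width):
        fh.write(seq[i:i + width] + "\n")


def generate_reference(length: int, gc: float = 0.42,
                       seed: int | np.random.Generator = 0) -> str:
    """I.i.d. random sequence with P(G or C) = ``gc``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc must lie in [0,1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _sample_position(rng: np.random.Generator, length: int,
                     regions: Sequence[Region], weights: Sequence[float]) -> int:
    """Sample a 1-based position from the region mixture (remaining mass is
    uniform over the background, i.e. outside every region)."""
    u = rng.random()
    acc = 0.0
    for region, w in zip(regions, weights):
        acc += w
        if u < acc:
            return int(rng.integers(region.start, region.end + 1))
    for _ in range(10_000):
        pos = int(rng.integers(1, length + 1))
        if not any(pos in r for r in regions):
            return pos
    raise SimulationError("no background positions available")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


_MAX_TRIES = 20_000


def simulate_fusion(tcf3_ref: str, pbx1_ref: str, bp_model: BreakpointModel,
                    j_model: JunctionModel, seed: int | np.random.Generator = 0,
                    foreign_db: Sequence[str] = (), p_reciprocal: float = 0.3,
                    event_id: str = "sim") -> FusionEvent:
    """Simulate one t(1;19)-like event.

    The primary derivative is ``tcf3_ref[:x] + insert + pbx1_ref[y-1:]`` with
    ``x``/``y`` the 1-based truth breakpoints. Junction context is rejected
    and resampled until the planted microhomology/insert is exactly what a
    maximal-overlap junction caller will recover; exceeding the retry budget
    raises :class:`SimulationError`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if bp_model.tcf3_length != len(tcf3_ref) or bp_model.pbx1_length != len(pbx1_ref):
        raise ValueError("model lengths do not match the provided references")
    donor, acceptor = tcf3_ref.upper(), pbx1_ref.upper()

    # --- junction feature draw (inversion/foreign exclude microhomology) ---
    u = rng.random()
    insert = ""
    insert_class = "none"
    mh = 0
    if u < j_model.p_inversion:
        insert_class = "inverted-segment"
    elif u < j_model.p_inversion + j_model.p_foreign:
        insert_class = "foreign"
        if not foreign_db:
            raise ValueError("foreign insert requested but foreign_db is empty")
    else:
        lengths, probs = zip(*j_model.mh_probs)
        mh = int(rng.choice(lengths, p=probs))
        if mh == 0 and rng.random() < j_model.p_insert:
            insert_class = "non-template"

    # --- insert content (sampled before breakpoint placement) ---
    if insert_class == "inverted-segment":
        if len(acceptor) < j_model.inversion_len + 2:
            raise SimulationError("acceptor too short for the inversion length")
        a = int(rng.integers(0, len(acceptor) - j_model.inversion_len + 1))
        insert = _revcomp(acceptor[a:a + j_model.inversion_len])
    elif insert_class == "foreign":
        src = foreign_db[int(rng.integers(0, len(foreign_db)))].upper()
        ln = min(j_model.foreign_insert_len, len(src))
        a = int(rng.integers(0, len(src) - ln + 1))
        insert = src[a:a + ln]
    elif insert_class == "non-template":
        insert = _random_seq(rng, int(rng.geometric(j_model.insert_geom_p)))

    # --- donor breakpoint (fixed-content inserts must mismatch the donor flank) ---
    for _ in range(_MAX_TRIES):
        x = _sample_position(rng, len(donor), [bp_model.tcf3_hotspot],
                             [bp_model.tcf3_hotspot_weight])
        if not mh + 1 <= x <= len(donor) - 1:
            continue
        if insert and insert_class != "non-template" and insert[0] == donor[x]:
            continue
        break
    else:
        raise SimulationError("could not place donor breakpoint")

    if insert_class == "non-template":
        # free insert content: resample until it cannot extend the donor anchor
        for _ in range(_MAX_TRIES):
            if insert[0] != donor[x]:
                break
            insert = _random_seq(rng, len(insert))
        else:  # pragma: no cover - 1/4 success chance per draw
            raise SimulationError("could not place non-template insert")

    # --- acceptor breakpoint honoring the junction contract ---
    y = _place_acceptor(rng, donor, acceptor, bp_model, x, mh, insert)

    der19 = donor[:x] + insert + acceptor[y - 1:]
    truth = TruthRecord(event_id=event_id, tcf3_break=x, pbx1_break=y,
                        microhomology_len=mh, inserted_seq=insert,
                        insert_class=insert_class,
                        reciprocal=False)

    der1 = None
    if rng.random() < p_reciprocal:
        der1 = acceptor[:y - 1] + donor[x:]
        truth = replace(truth, reciprocal=True)
    return FusionEvent(der19=der19, der1=der1, truth=truth)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _place_acceptor(rng: np.random.Generator, donor: str, acceptor: str,
                    bp_model: BreakpointModel, x: int, mh: int, insert: str) -> int:
    """Sample the 1-based first retained acceptor base ``y`` such that the
    junction shows exactly ``mh`` bases of microhomology (no insert case) or
    clean anchoring around the insert."""
    for _ in range(_MAX_TRIES):
        y = _sample_position(rng, len(acceptor), bp_model.pbx1_clusters,
                             bp_model.pbx1_cluster_weights)
        if not mh + 2 <= y <= len(acceptor):
            continue
        y0 = y - 1  # 0-based index of first retained acceptor base
        if insert:
            # the insert's last base must not extend the acceptor anchor
            if insert[-1] != acceptor[y0 - 1]:
                return y
            continue
        # forward extension must stop exactly at the junction
        if acceptor[y0] == donor[x]:
            continue
        # exactly mh matching bases upstream of the junction
        if any(acceptor[y0 - 1 - i] != donor[x - 1 - i] for i in range(mh)):
            continue
        if x - 1 - mh >= 0 and y0 - 1 - mh >= 0 and acceptor[y0 - 1 - mh] == donor[x - 1 - mh]:
            continue
        return y
    raise SimulationError(f"could not place acceptor breakpoint (mh={mh})")


def simulate_cohort(n: int, bp_model: BreakpointModel | None = None,
                    j_model: JunctionModel | None = None, seed: int = 0,
                    gc: float = 0.42, p_reciprocal: float = 0.3,
                    n_foreign: int = 1, foreign_len: int = 2_000) -> Cohort:
    """Simulate ``n`` independent fusion events on one pair of references."""
    if n < 0:
        raise ValueError("n must be >= 0")
    bp_model = bp_model or BreakpointModel.scaled()
    j_model = j_model or JunctionModel()
    rng = np.random.default_rng(seed)
    tcf3_ref = generate_reference(bp_model.tcf3_length, gc, rng)
    pbx1_ref = generate_reference(bp_model.pbx1_length, gc, rng)
    foreign_db = tuple(_random_seq(rng, foreign_len) for _ in range(n_foreign))
    events = tuple(
        simulate_fusion(tcf3_ref, pbx1_ref, bp_model, j_model, rng,
                        foreign_db=foreign_db, p_reciprocal=p_reciprocal,
                        event_id=f"sim{i:05d}")
        for i in range(n))
    return Cohort(tcf3_ref=tcf3_ref, pbx1_ref=pbx1_ref,
                  foreign_db=foreign_db, events=events)
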