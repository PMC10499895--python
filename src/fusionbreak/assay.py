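"""In-silico restriction digest, enzyme screening and PCR product prediction.

Models the long range-inverse PCR (LRI-PCR) workflow: digest genomic DNA,
self-ligate fragments into circles, and amplify across the ligation junction
with divergent primers. Also predicts ordinary (convergent) multiplex
long-range products on a derivative chromosome.

The simulator is deterministic: exact full-length primer annealing, complete
digestion, no methylation or ligation-efficiency modeling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

from Bio.Seq import Seq

__all__ = [
    "RestrictionEnzyme",
    "Primer",
    "Fragment",
    "AmpliconPrediction",
    "ScreenConfig",
    "ScreenResult",
    "load_enzyme_db",
    "load_primers",
    "screen_enzymes",
    "digest",
    "find_primer_sites",
    "inverse_pcr_product",
    "control_band_sizes",
    "breakpoint_detectability",
    "multiplex_products",
    "revcomp",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: IUPAC recognition site plus strand cut offsets.

    ``cut_offset_top``/``cut_offset_bottom`` count bases from the 5' end of
    the recognition site to the cut on the top/bottom strand (0..site length).
    """

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int

    def __post_init__(self) -> None:
        site = self.recognition.upper()
        if not site or any(c not in _IUPAC for c in site):
            raise ValueError(f"{self.name}: invalid recognition {self.recognition!r}")
        for off in (self.cut_offset_top, self.cut_offset_bottom):
            if not 0 <= off <= len(site):
                raise ValueError(f"{self.name}: cut offset {off} outside site")
        object.__setattr__(self, "recognition", site)

    @property
    def is_palindromic(self) -> bool:
        # Degenerate sites compare as IUPAC strings (CCANNNNNNTGG is its own
        # reverse complement under IUPAC complement rules).
        comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N", "R": "Y",
                "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K", "B": "V",
                "V": "B", "D": "H", "H": "D"}
        return self.recognition == "".join(comp[c] for c in reversed(self.recognition))

    @property
    def is_sticky(self) -> bool:
        return self.cut_offset_top != self.cut_offset_bottom

    @property
    def is_degenerate(self) -> bool:
        return any(c not in "ACGT" for c in self.recognition)

    def site_pattern(self) -> re.Pattern:
        body = "".join(_IUPAC[c] for c in self.recognition)
        return re.compile(f"(?=({body}))")  # lookahead: overlapping sites

    def site_starts(self, seq: str) -> list[int]:
        """0-based start positions of recognition sites on the plus strand."""
        return [m.start() for m in self.site_pattern().finditer(seq.upper())]

    def cut_positions(self, seq: str) -> list[int]:
        """0-based boundaries (between bases) of top-strand cuts."""
        return [s + self.cut_offset_top for s in self.site_starts(seq)]


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 15:
            raise ValueError(f"primer {self.name}: length {len(seq)} < 15")
        if any(c not in "ACGT" for c in seq):
            raise ValueError(f"primer {self.name}: non-ACGT symbol")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


EndLabel = Literal["enzyme", "molecule_end", "circular"]


@dataclass(frozen=True)
class Fragment:
    """A digest fragment. ``start`` is the 0-based offset on the parent
    (for circular digests, the parent linearized as given)."""

    start: int
    sequence: str
    left_end: EndLabel
    right_end: EndLabel

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def circularizable(self) -> bool:
        return self.left_end == "enzyme" and self.right_end == "enzyme"


@dataclass(frozen=True)
class AmpliconPrediction:
    forward: str
    reverse: str
    size: int
    span: str
    contains_junction: bool


def digest(seq: str, enzyme: RestrictionEnzyme,
           topology: Literal["linear", "circular"] = "linear") -> list[Fragment]:
    """Cut a sequence at every recognition site.

    Linear molecules with n sites yield n+1 fragments (outermost fragments
    keep their molecule ends); circular molecules yield n fragments, or the
    uncut circle when no site exists. Fragment lengths always sum to the
    parent length.
    """
    seq = seq.upper()
    L = len(seq)
    if topology == "linear":
        cuts = sorted({c for c in enzyme.cut_positions(seq) if 0 < c < L})
        bounds = [0, *cuts, L]
        frags = []
        for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
            frags.append(Fragment(
                start=a, sequence=seq[a:b],
                left_end="molecule_end" if i == 0 else "enzyme",
                right_end="molecule_end" if b == L else "enzyme",
            ))
        return frags
    if topology == "circular":
        if L == 0:
            return []
        # scan the doubled sequence so sites spanning the origin are seen
        ext = seq + seq[: max(len(enzyme.recognition) - 1, 0)]
        cuts = sorted({(s + enzyme.cut_offset_top) % L
                       for s in enzyme.site_starts(ext) if s < L})
        if not cuts:
            return [Fragment(start=0, sequence=seq, left_end="circular", right_end="circular")]
        frags = []
        for a, b in zip(cuts, cuts[1:] + [cuts[0] + L]):
            frag_seq = seq[a:b] if b <= L else seq[a:] + seq[: b - L]
            frags.append(Fragment(start=a, sequence=frag_seq,
                                  left_end="enzyme", right_end="enzyme"))
        return frags
    raise ValueError(f"unknown topology {topology!r}")


def find_primer_sites(seq: str, primer: Primer) -> list[tuple[int, str]]:
    """Exact-match binding sites of a primer on both strands.

    Returns ``(position, strand)`` where position is the 1-based plus-strand
    coordinate of the primer's 5' base: for a plus-strand hit that is the
    start of the match; for a minus-strand hit (the primer's reverse
    complement on the plus strand) it is the end of the match.
    """
    seq = seq.upper()
    hits: list[tuple[int, str]] = []
    for m in re.finditer(f"(?={re.escape(primer.sequence)})", seq):
        hits.append((m.start() + 1, "+"))
    for m in re.finditer(f"(?={re.escape(revcomp(primer.sequence))})", seq):
        hits.append((m.start() + len(primer), "-"))
    return sorted(hits)


class AmbiguousPrimingError(ValueError):
    """A primer binds a fragment more than once."""


def _unique_circular_site(fragment_seq: str, primer: Primer, strand: str) -> int | None:
    """1-based 5'-base coordinate of the single binding site on the
    circularized fragment, or None. Sites spanning the linearization point
    are found by scanning the doubled sequence."""
    L = len(fragment_seq)
    ext = fragment_seq + fragment_seq[: min(len(primer) - 1, L)]
    hits = {((pos - 1) % L) + 1 for pos, s in find_primer_sites(ext, primer)
            if s == strand and pos <= L + (len(primer) - 1)}
    # find_primer_sites on the extension can report a minus-strand 5' end past
    # L even for a site starting within the first copy; the mod folds it back.
    if len(hits) > 1:
        raise AmbiguousPrimingError(f"primer {primer.name} binds {len(hits)} times")
    return hits.pop() if hits else None


def inverse_pcr_product(fragment: Fragment, forward: Primer, reverse: Primer,
                        junction_only: bool = True) -> AmpliconPrediction | None:
    """Predict the product amplified on the self-ligated (circular) fragment.

    The fragment must circularize (both ends enzyme junctions). On the
    circle a forward plus-strand site and a reverse minus-strand site define
    exactly one product: the arc from the forward primer's 5' base, in plus
    orientation, to the reverse primer's 5' base, inclusive
    (``((p_r - p_f) mod L) + 1`` bases). With ``junction_only`` (the
    inverse-PCR contract) the product is reported only when that arc crosses
    the ligation junction between the fragment ends; a convergent pair whose
    product lies within the fragment is ordinary PCR and yields None.
    """
    if not fragment.circularizable:
        return None
    L = len(fragment)
    p_f = _unique_circular_site(fragment.sequence, forward, "+")
    p_r = _unique_circular_site(fragment.sequence, reverse, "-")
    if p_f is None or p_r is None:
        return None
    crosses = p_r < p_f or p_f + len(forward) - 1 > L or p_r - len(reverse) + 1 < 1
    if junction_only and not crosses:
        return None
    size = ((p_r - p_f) % L) + 1
    return AmpliconPrediction(
        forward=forward.name, reverse=reverse.name, size=size,
        span=f"circle arc {p_f}->{p_r} of fragment@{fragment.start}",
        contains_junction=crosses,
    )


def control_band_sizes(reference_seq: str, enzyme: RestrictionEnzyme,
                       primer_pairs: Sequence[tuple[Primer, Primer]],
                       ) -> dict[tuple[str, str], int | None]:
    """Predict inverse-PCR control bands on unrearranged reference DNA.

    For each (forward, reverse) pair: digest, find the fragment carrying both
    primers in productive orientation, circularize it and measure the
    product. Pairs whose primers do not share a circularizable fragment map
    to ``None``.
    """
    frags = digest(reference_seq, enzyme, "linear")
    out: dict[tuple[str, str], int | None] = {}
    for fwd, rev in primer_pairs:
        out[(fwd.name, rev.name)] = None
        for frag in frags:
            if not frag.circularizable:
                continue
            product = inverse_pcr_product(frag, fwd, rev)
            if product is not None:
                out[(fwd.name, rev.name)] = product.size
                break
    return out


@dataclass(frozen=True)
class ScreenConfig:
    max_recognition_len: int = 6   # "frequent cutter" threshold
    max_fragment: int = 10_000     # largest workable long-range product


@dataclass(frozen=True)
class ScreenResult:
    enzyme: RestrictionEnzyme
    left_distance: int    # bp from the nearest upstream cut to region start
    right_distance: int   # bp from region end to the nearest downstream cut

    @property
    def total_flank(self) -> int:
        return self.left_distance + self.right_distance


def screen_enzymes(enzyme_db: Sequence[RestrictionEnzyme], region_seq: str,
                   region_start: int, region_end: int,
                   config: ScreenConfig = ScreenConfig()) -> list[ScreenResult]:
    """Select enzymes suitable for inverse PCR around a target region.

    An enzyme passes iff it is palindromic, non-degenerate, leaves sticky
    ends, recognizes at most ``max_recognition_len`` bases, and cuts at
    least once on each side of the region within ``max_fragment`` bp.
    Results are ranked by total flanking distance (tightest bracket first).
    ``region_start``/``region_end`` are 1-based inclusive on ``region_seq``.
    """
    if not 1 <= region_start <= region_end <= len(region_seq):
        raise ValueError("region outside sequence")
    results = []
    for enz in enzyme_db:
        if not (enz.is_palindromic and not enz.is_degenerate and enz.is_sticky
                and len(enz.recognition) <= config.max_recognition_len):
            continue
        cuts = enz.cut_positions(region_seq)  # 0-based boundaries
        left = [c for c in cuts if c <= region_start - 1]
        right = [c for c in cuts if c >= region_end]
        if not left or not right:
            continue
        ld = (region_start - 1) - max(left)
        rd = min(right) - region_end
        if ld > config.max_fragment or rd > config.max_fragment:
            continue
        results.append(ScreenResult(enzyme=enz, left_distance=ld, right_distance=rd))
    return sorted(results, key=lambda r: (r.total_flank, r.enzyme.name))


@dataclass(frozen=True)
class DetectabilityResult:
    detectable: bool
    size: int | None
    reason: str


def breakpoint_detectability(der_seq: str, junction_pos: int,
                             enzyme: RestrictionEnzyme, forward: Primer,
                             reverse: Primer, max_size: int = 10_000,
                             ) -> DetectabilityResult:
    """Decide whether an LRI-PCR assay would capture a fusion junction.

    Detectable iff the digest fragment containing ``junction_pos`` (1-based
    on the derivative) also carries both primers in productive orientation,
    the predicted product covers the junction, and its size is within
    ``max_size``.
    """
    if not 1 <= junction_pos <= len(der_seq):
        raise ValueError("junction_pos outside derivative sequence")
    for frag in digest(der_seq, enzyme, "linear"):
        if frag.start < junction_pos <= frag.start + len(frag):
            break
    else:  # pragma: no cover - digest always tiles the molecule
        raise AssertionError("no fragment contains the junction")
    if not frag.circularizable:
        return DetectabilityResult(False, None, "junction fragment has a molecule end")
    product = inverse_pcr_product(frag, forward, reverse, junction_only=False)
    if product is None:
        return DetectabilityResult(False, None, "primers do not bind the junction fragment")
    jp = junction_pos - frag.start  # 1-based within fragment
    p_f = _unique_circular_site(frag.sequence, forward, "+")
    p_r = _unique_circular_site(frag.sequence, reverse, "-")
    if (jp - p_f) % len(frag) > (p_r - p_f) % len(frag):
        return DetectabilityResult(False, None, "junction outside the amplified arc")
    if product.size > max_size:
        return DetectabilityResult(False, product.size, f"product {product.size} bp > {max_size}")
    return DetectabilityResult(True, product.size, "ok")


def multiplex_products(der_seq: str, forward: Primer,
                       reverse_panel: Sequence[Primer], junction_pos: int,
                       max_size: int = 10_000) -> list[AmpliconPrediction]:
    """Predict ordinary long-range products bracketing a fusion junction.

    One prediction per (forward, panel primer) pair whose convergent product
    spans ``junction_pos`` with size <= ``max_size``; sorted by size.
    """
    seq = der_seq.upper()
    fwd_hits = [p for p, s in find_primer_sites(seq, forward) if s == "+"]
    preds: list[AmpliconPrediction] = []
    for rev in reverse_panel:
        rev_hits = [p for p, s in find_primer_sites(seq, rev) if s == "-"]
        for p_f in fwd_hits:
            for p_r in rev_hits:
                size = p_r - p_f + 1
                if p_f < p_r and p_f <= junction_pos <= p_r and size <= max_size:
                    preds.append(AmpliconPrediction(
                        forward=forward.name, reverse=rev.name, size=size,
                        span=f"[{p_f}..{p_r}]", contains_junction=True))
    return sorted(preds, key=lambda a: a.size)


def load_enzyme_db(path: str | Path | None = None) -> list[RestrictionEnzyme]:
    """Load the enzyme DB TSV (name, recognition, cut_offset_top, cut_offset_bottom)."""
    if path is None:
        ref = resources.files("fusionbreak.data").joinpath("enzymes.tsv")
        with resources.as_file(ref) as p:
            return load_enzyme_db(p)
    enzymes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("name\t"):
            continue
        name, recognition, top, bottom, *_ = line.split("\t")
        enzymes.append(RestrictionEnzyme(name, recognition, int(top), int(bottom)))
    return enzymes


def load_primers(path: str | Path | None = None) -> dict[str, Primer]:
    """Load the primer TSV (name, sequence, role); returns name -> Primer."""
    if path is None:
        ref = resources.files("fusionbreak.data").joinpath("lri_primers.tsv")
        with resources.as_file(ref) as p:
            return load_primers(p)
    primers = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("name\t"):
            continue
        name, sequence, *_ = line.split("\t")
        primers[name] = Primer(name, sequence)
    return primers
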