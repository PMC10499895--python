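"""Fusion-junction characterization: microhomology and insertions.

Given a derivative sequence anchored on both sides (it begins with a prefix
of the donor reference and ends with a suffix of the acceptor reference),
the junction is described by pure string arithmetic: with
``x = LCP(der, donor)`` and ``y = LCS(der, acceptor)``,

* ``x + y >= len(der)``  ->  microhomology of ``x + y - len(der)`` bp and no
  inserted bases (the breakpoint is ambiguous over the homology range);
* otherwise              ->  inserted bases ``der[x .. len(der)-y]`` and no
  microhomology.

The maximal-microhomology interpretation is reported: ``donor_break`` is the
LCP length (the 3'-most donor coordinate), with the ambiguity range given
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .assay import revcomp

__all__ = ["JunctionCall", "AnchoringError", "characterize_junction", "classify_insert"]

INSERT_CLASSES = ("none", "non-template", "inverted-segment", "foreign")


class AnchoringError(ValueError):
    """The derivative does not start in the donor / end in the acceptor."""


@dataclass(frozen=True)
class JunctionCall:
    donor_break: int                 # last donor base retained (1-based, max-mh)
    donor_break_range: tuple[int, int]
    acceptor_break: int              # first acceptor base retained (1-based, max-mh)
    acceptor_break_range: tuple[int, int]
    microhomology_len: int
    inserted_seq: str
    insert_class: str

    def __post_init__(self) -> None:
        if self.microhomology_len > 0 and self.inserted_seq:
            raise ValueError("microhomology and insertion are mutually exclusive")
        if self.insert_class not in INSERT_CLASSES:
            raise ValueError(f"unknown insert class {self.insert_class!r}")


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def characterize_junction(der_seq: str, donor_ref: str, acceptor_ref: str,
                          foreign_db: Sequence[str] | None = None,
                          min_insert_match: int = 10) -> JunctionCall:
    """Call the junction of a pre-anchored derivative sequence."""
    der, donor, acceptor = der_seq.upper(), donor_ref.upper(), acceptor_ref.upper()
    x = _lcp(der, donor)
    y = _lcs(der, acceptor)
    if x == 0:
        raise AnchoringError("derivative does not begin with donor sequence")
    if y == 0:
        raise AnchoringError("derivative does not end with acceptor sequence")

    L = len(der)
    if x + y >= L:
        mh = x + y - L
        insert = ""
    else:
        mh = 0
        insert = der[x:L - y]

    acceptor_break = len(acceptor) - y + 1
    call = JunctionCall(
        donor_break=x,
        donor_break_range=(x - mh, x),
        acceptor_break=acceptor_break,
        acceptor_break_range=(acceptor_break, acceptor_break + mh),
        microhomology_len=mh,
        inserted_seq=insert,
        insert_class="none" if not insert else classify_insert(
            insert, donor, acceptor, foreign_db, min_insert_match),
    )
    return call


def classify_insert(inserted_seq: str, donor_ref: str, acceptor_ref: str,
                    foreign_db: Sequence[str] | None = None,
                    min_len: int = 10) -> str:
    """Classify junction-inserted bases.

    inverted-segment: the insert (at least ``min_len`` bp) is the reverse
    complement of a contiguous stretch of either parental reference;
    foreign: it matches a sequence in ``foreign_db``; anything else (and
    every insert shorter than ``min_len``) is called non-template.
    """
    if not inserted_seq:
        raise ValueError("inserted_seq must be non-empty")
    insert = inserted_seq.upper()
    if len(insert) >= min_len:
        rc = revcomp(insert)
        if rc in donor_ref.upper() or rc in acceptor_ref.upper():
            return "inverted-segment"
        for foreign in foreign_db or ():
            if insert in foreign.upper():
                return "foreign"
    return "non-template"
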