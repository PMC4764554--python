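"""Hexamer motif scanning in TC-anchored 3'UTR windows.

PTBP1 binds degenerate CU-rich elements; its six highest-affinity hexamers
(UUCUCU, UCUUCU, UCUCUU, UCUCUG, CUUUCU, CUUCUC — together accounting for
more than half of observed PTBP1 CLIP peaks) are the default scan set.
Scanning reports every occurrence, including overlapping ones, as 0-based
offsets into the 3'UTR (offset 0 = first base after the stop codon).

Window membership uses a full-containment rule: a hit counts toward window
[a, b) only if its entire 6-nt extent lies inside the window, so a hit
starting at offset 47 does not belong to [0, 50).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DEFAULT_HEXAMERS",
    "TC_WINDOWS",
    "HexamerSet",
    "MotifHit",
    "scan_hexamers",
    "hexamer_presence",
    "write_hits_table",
    "write_presence_table",
]

#: the six top PTBP1 CLIP hexamers (DNA alphabet)
DEFAULT_HEXAMERS = ("TTCTCT", "TCTTCT", "TCTCTT", "TCTCTG", "CTTTCT", "CTTCTC")

#: TC-anchored windows used throughout the positional analyses, in nt
TC_WINDOWS: dict[str, tuple[int, int]] = {
    "tc_400": (0, 400),
    "tc_150": (0, 150),
    "tc_50": (0, 50),
    "tc_50_100": (50, 100),
}


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class HexamerSet:
    """A set of unique 6-nt DNA motifs (RNA input U is normalized to T)."""

    motifs: tuple[str, ...] = DEFAULT_HEXAMERS

    def __post_init__(self) -> None:
        norm = tuple(_normalize(m) for m in self.motifs)
        for m in norm:
            if len(m) != 6 or set(m) - set("ACGT"):
                raise ValueError(f"not a 6-nt ACGT motif: {m!r}")
        if len(set(norm)) != len(norm):
            raise ValueError("duplicate motifs in hexamer set")
        object.__setattr__(self, "motifs", norm)

    @property
    def pattern(self) -> re.Pattern:
        # lookahead so overlapping occurrences are all reported
        return re.compile("(?=(" + "|".join(self.motifs) + "))")


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence: 0-based start offset downstream of the TC."""

    transcript_id: str
    offset: int
    motif: str


def scan_hexamers(
    seq: str, hexamers: HexamerSet | None = None, transcript_id: str = ""
) -> list[MotifHit]:
    """All (overlapping) hexamer occurrences in a 3'UTR sequence, sorted by
    offset.  N bases never match."""
    hexamers = hexamers or HexamerSet()
    s = _normalize(seq)
    return [
        MotifHit(transcript_id, m.start(), m.group(1))
        for m in hexamers.pattern.finditer(s)
    ]


def hexamer_presence(
    seq: str,
    window: tuple[int, int],
    hexamers: HexamerSet | None = None,
    transcript_id: str = "",
) -> dict:
    """Presence flag and count of hexamer hits fully contained in offsets
    [a, b) of a 3'UTR sequence.

    A window extending beyond the available sequence is truncated and the
    result flagged (``truncated=True``).
    """
    a, b = window
    if not (0 <= a < b):
        raise ValueError(f"bad window {window}")
    truncated = b > len(seq)
    hits = [h for h in scan_hexamers(seq, hexamers, transcript_id)
            if h.offset >= a and h.offset + 6 <= b]
    return {
        "transcript_id": transcript_id,
        "window": (a, b),
        "present": bool(hits),
        "count": len(hits),
        "truncated": truncated,
    }


def write_hits_table(hits: Iterable[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\toffset\tmotif\n")
        for h in hits:
            fh.write(f"{h.transcript_id}\t{h.offset}\t{h.motif}\n")


def write_presence_table(
    sequences: Mapping[str, str],
    windows: Mapping[str, tuple[int, int]],
    path: str | Path,
    hexamers: HexamerSet | None = None,
) -> None:
    """Per-transcript presence flags for each named TC-anchored window."""
    names = list(windows)
    with open(path, "w") as fh:
        fh.write("transcript_id\t" + "\t".join(names) + "\n")
        for tid in sorted(sequences):
            row = [
                str(int(hexamer_presence(sequences[tid], windows[n], hexamers)["present"]))
                for n in names
            ]
            fh.write(tid + "\t" + "\t".join(row) + "\n")
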