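"""Framework / CDR segmentation of a VHH (nanobody) variable domain.

A VHH domain of ~120-130 residues partitions into seven contiguous
segments: FR1, CDR1, FR2, CDR2, FR3, CDR3, FR4.  Published per-structure
CDR bounds are supplied as explicit overrides; when none are given a
light-weight anchor heuristic is applied, keyed on the two conserved
framework cysteines and the FR4 "WGxG" motif.  The heuristic is a
convenience, not a numbering scheme — any serious analysis should pass the
scheme-specific ranges it trusts.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class RegionMap:
    """Ordered FR/CDR segments as inclusive 1-based ranges covering 1..L."""

    segments: dict  # name -> (start, end)

    def __post_init__(self):
        raw = {k: (int(v[0]), int(v[1])) for k, v in dict(self.segments).items()}
        if set(raw) != set(REGION_ORDER):
            raise AnnotationError(
                f"regions must be exactly {REGION_ORDER}; got {sorted(raw)}")
        segs = {name: raw[name] for name in REGION_ORDER}
        prev_end = 0
        for name in REGION_ORDER:
            start, end = segs[name]
            if start != prev_end + 1:
                raise AnnotationError(
                    f"{name} starts at {start}, expected {prev_end + 1} "
                    "(segments must be contiguous and non-overlapping)")
            if end < start:
                raise AnnotationError(f"{name} has end {end} < start {start}")
            prev_end = end
        object.__setattr__(self, "segments", segs)

    @property
    def length(self) -> int:
        return self.segments["FR4"][1]

    def __getitem__(self, name: str):
        return self.segments[name]

    def items(self):
        return self.segments.items()

    def cdr_names(self):
        return [n for n in REGION_ORDER if n.startswith("CDR")]

    def to_json(self) -> str:
        return json.dumps({k: list(v) for k, v in self.segments.items()})

    @classmethod
    def from_json(cls, text: str) -> "RegionMap":
        return cls(json.loads(text))


def _heuristic_regions(sequence: str) -> RegionMap:
    L = len(sequence)
    # first conserved cysteine, expected near position 22
    cys1 = min((i for i, c in enumerate(sequence[:35], start=1) if c == "C"),
               key=lambda i: abs(i - 22), default=None)
    # second conserved cysteine, expected in the high-80s/90s
    cand2 = [i for i, c in enumerate(sequence, start=1) if c == "C" and 70 <= i <= L - 15]
    cys2 = min(cand2, key=lambda i: abs(i - 92)) if cand2 else None
    wgxg = None
    m = None
    for m in re.finditer(r"WG.G", sequence):
        wgxg = m.start() + 1  # 1-based position of the tryptophan
    if cys1 is None or cys2 is None or wgxg is None or not (cys1 < cys2 < wgxg):
        raise AnnotationError(
            "annotation failed, supply override: anchor motifs "
            "(framework cysteines / WGxG) not found")
    cdr1 = (cys1 + 4, cys1 + 14)
    cdr2 = (cdr1[1] + 19, cdr1[1] + 26)
    cdr3 = (cys2 + 3, wgxg - 1)
    if not (cdr1[1] < cdr2[0] and cdr2[1] < cdr3[0] and cdr3[1] < L):
        raise AnnotationError(
            "annotation failed, supply override: anchor-derived segments "
            "are inconsistent")
    return RegionMap({
        "FR1": (1, cdr1[0] - 1),
        "CDR1": cdr1,
        "FR2": (cdr1[1] + 1, cdr2[0] - 1),
        "CDR2": cdr2,
        "FR3": (cdr2[1] + 1, cdr3[0] - 1),
        "CDR3": cdr3,
        "FR4": (cdr3[1] + 1, L),
    })


def annotate_regions(sequence: str, override=None) -> RegionMap:
    """Partition a VHH sequence into FR1..FR4 / CDR1..CDR3.

    Parameters
    ----------
    sequence : str
        One-letter amino-acid sequence, 100-140 residues.
    override : mapping, optional
        Explicit {name: (start, end)} ranges (1-based inclusive); they are
        validated to be contiguous, ordered, and to cover 1..L exactly.
    """
    L = len(sequence)
    if not 100 <= L <= 140:
        raise AnnotationError(
            f"sequence length {L} outside the VHH domain range 100-140")
    if override is not None:
        rm = RegionMap(override)
        if rm.length != L:
            raise AnnotationError(
                f"override covers 1..{rm.length} but sequence has {L} residues")
        return rm
    return _heuristic_regions(sequence)
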