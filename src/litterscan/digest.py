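"""In-silico double-digest (ddRAD) restriction fragment prediction.

Given a genome sequence and two restriction enzymes, predict the fragments a
complete double digest would produce and the subset falling in a
size-selection window.  Defaults are the classic ddRAD pair PstI
(CTGCA^G, cutting after position 5 of the recognition site) and MspI
(C^CGG, cutting after position 1); the sequenceable ddRAD class is the set
of fragments with one PstI end and one MspI end inside the window
(300 +/- 50 bp by default).  Coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import pandas as pd
from Bio import SeqIO

TERMINUS = "sequence-terminus"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A recognition sequence plus the cut offset within it (top strand)."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if set(self.recognition) - set("ACGT"):
            raise ValueError(f"{self.name}: recognition must be over ACGT")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(f"{self.name}: cut offset outside recognition site")

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == self.recognition.translate(_COMPLEMENT)[::-1]


PSTI = RestrictionEnzyme("PstI", "CTGCAG", 5)
MSPI = RestrictionEnzyme("MspI", "CCGG", 1)


class Fragment(NamedTuple):
    sequence_id: str
    start: int
    end: int
    length: int
    end5_enzyme: str
    end3_enzyme: str


@dataclass
class FragmentSet:
    """Digest fragments, optionally restricted to a size-selection window."""

    fragments: list[Fragment]
    window_center: int | None = None
    window_halfwidth: int | None = None

    def __len__(self) -> int:
        return len(self.fragments)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.fragments, columns=Fragment._fields)

    def to_bed(self, path: str | Path) -> None:
        """BED-like TSV: sequence, start, end, end-enzyme pair as the name."""
        with open(path, "w") as fh:
            for f in self.fragments:
                fh.write(
                    f"{f.sequence_id}\t{f.start}\t{f.end}\t"
                    f"{f.end5_enzyme}/{f.end3_enzyme}\t{f.length}\n"
                )

    def summary(self) -> dict:
        df = self.to_dataframe()
        by_ends: dict[str, int] = {}
        if len(df):
            key = df.end5_enzyme + "/" + df.end3_enzyme
            by_ends = key.value_counts().to_dict()
        return {
            "n_fragments": len(self.fragments),
            "by_end_class": by_ends,
            "window_center": self.window_center,
            "window_halfwidth": self.window_halfwidth,
            "mean_length": float(df.length.mean()) if len(df) else None,
        }


def _cut_positions(sequence: str, enzyme: RestrictionEnzyme) -> list[tuple[int, str]]:
    cuts = []
    site, off = enzyme.recognition, enzyme.cut_offset
    start = sequence.find(site)
    while start != -1:
        cuts.append((start + off, enzyme.name))
        start = sequence.find(site, start + 1)
    if not enzyme.is_palindromic:
        # a bottom-strand site reads as the reverse complement on the top
        # strand, cut mirrored from the other end of the site
        rc = enzyme.recognition.translate(_COMPLEMENT)[::-1]
        off_rc = len(site) - off
        start = sequence.find(rc)
        while start != -1:
            cuts.append((start + off_rc, enzyme.name))
            start = sequence.find(rc, start + 1)
    return cuts


def digest(
    sequence: str,
    site1: RestrictionEnzyme = PSTI,
    site2: RestrictionEnzyme = MSPI,
    sequence_id: str = "seq",
    on_ambiguous: str = "skip",
) -> FragmentSet:
    """Complete double digest of one sequence.

    Cut positions of both enzymes are pooled and sorted; fragments are the
    intervals between consecutive cuts plus the two terminal pieces (ends
    labelled "sequence-terminus").  Ambiguity codes in the sequence either
    never match (``on_ambiguous="skip"``, default) or raise
    (``on_ambiguous="error"``).  When both enzymes cut at the same position
    the label of ``site1`` wins (documented tie-break); zero-length pieces
    are dropped, which keeps the fragment-length sum equal to the sequence
    length.
    """
    if on_ambiguous not in ("skip", "error"):
        raise ValueError("on_ambiguous must be 'skip' or 'error'")
    sequence = sequence.upper()
    if on_ambiguous == "error" and set(sequence) - set("ACGT"):
        bad = sorted(set(sequence) - set("ACGT"))
        raise ValueError(f"ambiguity codes in sequence: {bad}")

    cuts: dict[int, str] = {}
    for enz in (site2, site1):  # site1 written last wins position ties
        for pos, name in _cut_positions(sequence, enz):
            cuts[pos] = name
    boundaries = sorted(p for p in cuts if 0 < p < len(sequence))

    frags: list[Fragment] = []
    prev, prev_label = 0, TERMINUS
    for pos in boundaries + [len(sequence)]:
        label = cuts.get(pos, TERMINUS) if pos != len(sequence) else TERMINUS
        if pos > prev:
            frags.append(Fragment(sequence_id, prev, pos, pos - prev, prev_label, label))
        prev, prev_label = pos, cuts.get(pos, TERMINUS)
    if not sequence:
        return FragmentSet([])
    return FragmentSet(frags)


def digest_fasta(
    path: str | Path,
    site1: RestrictionEnzyme = PSTI,
    site2: RestrictionEnzyme = MSPI,
    on_ambiguous: str = "skip",
) -> FragmentSet:
    """Digest every record of a (multi-)FASTA file."""
    frags: list[Fragment] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        frags.extend(digest(str(rec.seq), site1, site2, rec.id, on_ambiguous).fragments)
    return FragmentSet(frags)


def select_ddrad(
    fragments: FragmentSet,
    center: int = 300,
    halfwidth: int = 50,
    require_mixed_ends: bool = False,
) -> FragmentSet:
    """Size-select fragments: keep lengths in [center - halfwidth,
    center + halfwidth] (inclusive bounds) and, when ``require_mixed_ends``,
    only fragments with one PstI-type and one MspI-type end — the class a
    ddRAD library actually sequences."""
    if center < 0 or halfwidth < 0:
        raise ValueError("center and halfwidth must be >= 0")
    lo, hi = center - halfwidth, center + halfwidth
    kept = []
    for f in fragments.fragments:
        if not lo <= f.length <= hi:
            continue
        if require_mixed_ends:
            ends = {f.end5_enzyme, f.end3_enzyme}
            if TERMINUS in ends or len(ends) != 2:
                continue
        kept.append(f)
    return FragmentSet(kept, window_center=center, window_halfwidth=halfwidth)
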