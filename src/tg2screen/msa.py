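"""Alignment I/O and alanine masking of a residue range.

Used to bias conformation-sensitive structure prediction: the columns of a
multiple sequence alignment that map onto a chosen residue range of the
target sequence (for TG2, Q276 through C336 — the region that differs
between the open and closed states) are rewritten to alanine, removing the
co-evolutionary signal for that segment.

FASTA alignments (all rows equal length) and A3M (lowercase letters are
insertion states relative to the match columns) are both supported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

GAP_CHARS = {"-", "."}


@dataclass
class Alignment:
    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids/seqs length mismatch")

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def n_match_columns(self) -> int:
        """Number of match-state columns (gaps + uppercase; lowercase chars
        are per-sequence insertions and do not form columns)."""
        counts = {sum(1 for ch in s if ch in GAP_CHARS or ch.isupper())
                  for s in self.seqs}
        if len(counts) != 1:
            raise ValueError(
                f"inconsistent match-column counts across sequences: {counts}")
        return counts.pop()

    def index_of(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise KeyError(f"sequence {seq_id!r} not in alignment "
                           f"(have {self.ids[:5]}...)") from None


def read_alignment(path: str | Path) -> Alignment:
    """Read a FASTA or A3M alignment (headers '>id ...')."""
    ids: list[str] = []
    seqs: list[str] = []
    current: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if ids:
                seqs.append("".join(current))
            ids.append(line[1:].split()[0])
            current = []
        else:
            current.append(line)
    if ids:
        seqs.append("".join(current))
    if not ids:
        raise ValueError(f"no sequences in {path}")
    aln = Alignment(ids=ids, seqs=seqs)
    aln.n_match_columns()  # validates consistency
    return aln


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n{seq}\n")


def _match_columns(seq: str) -> list[int]:
    """Positions in ``seq`` that are match states (uppercase or gap)."""
    return [i for i, ch in enumerate(seq)
            if ch in GAP_CHARS or ch.isupper()]


def mask_msa_alanine(aln: Alignment, target_id: str,
                     start_res: int = 276, end_res: int = 336,
                     expected_start: str | None = None,
                     expected_end: str | None = None,
                     all_sequences: bool = True) -> Alignment:
    """Replace the alignment columns covering target residues
    ``start_res``..``end_res`` (1-based, counted over the target's non-gap
    positions) with alanine.

    Gaps and insertion states are untouched. With ``all_sequences=True``
    (default, the stronger conformational bias) every sequence's residue in
    a masked column becomes 'A'; otherwise only the target's.
    ``expected_start``/``expected_end`` guard against off-by-one errors by
    checking the target letter at the range ends (for TG2/P21980 numbering:
    Q at 276, C at 336).
    """
    ti = aln.index_of(target_id)
    target = aln.seqs[ti]
    if not (1 <= start_res <= end_res):
        raise ValueError(f"bad residue range {start_res}..{end_res}")

    # map target residue number -> match-column index
    res_to_col: dict[int, int] = {}
    res = 0
    col = -1
    for ch in target:
        if ch in GAP_CHARS:
            col += 1
            continue
        if ch.isupper():
            col += 1
            res += 1
            res_to_col[res] = col
        else:
            # lowercase insertion in the target: a residue without a column
            res += 1
    if end_res > res:
        raise ValueError(
            f"range end {end_res} exceeds target length {res}")

    for bound, expected in ((start_res, expected_start), (end_res, expected_end)):
        if expected is None:
            continue
        c = res_to_col.get(bound)
        letter = target[_match_columns(target)[c]] if c is not None else None
        if letter != expected.upper():
            raise ValueError(
                f"guard mismatch: target residue {bound} is {letter!r}, "
                f"expected {expected!r}")

    mask_cols = {res_to_col[r] for r in range(start_res, end_res + 1)
                 if r in res_to_col}
    new_seqs = []
    for si, seq in enumerate(aln.seqs):
        if not all_sequences and si != ti:
            new_seqs.append(seq)
            continue
        chars = list(seq)
        cols = _match_columns(seq)
        for mc in mask_cols:
            pos = cols[mc]
            if chars[pos] not in GAP_CHARS:
                chars[pos] = "A"
        new_seqs.append("".join(chars))
    return Alignment(ids=list(aln.ids), seqs=new_seqs)
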