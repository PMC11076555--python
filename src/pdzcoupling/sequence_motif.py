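"""Degenerate-template scanning for internal PDZ-binding motifs.

PDZ domains canonically grip a partner's free C-terminal carboxylate, but
some (Dvl2's among them) also bind *internal* peptides in which an aspartate
side chain mimics that carboxylate. The scanner searches protein sequences
with degenerate residue-class templates derived from phage-display
consensus motifs and scores candidate windows with conservative-substitution
credit, because internal-motif matches are rarely exact.

Peptide residues are numbered relative to the carboxylate-mimicking anchor:
the anchor aspartate is P0, residues toward the C-terminus are P1, P2, ...
and residues toward the N-terminus are P-1, P-2, ...
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "ProteinSequence",
    "ResidueClassTable",
    "MotifTemplate",
    "MotifHit",
    "PdzPositionMap",
    "DEFAULT_TEMPLATES",
    "CONSERVATIVE_GROUPS",
    "parse_template",
    "scan",
    "assign_pdz_positions",
    "conservation_profile",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Fixed conservative-substitution groups used for partial credit.
CONSERVATIVE_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("DE"), frozenset("NQ"), frozenset("ST"),
    frozenset("KR"), frozenset("FYW"), frozenset("AVLIM"),
)


@dataclasses.dataclass
class ProteinSequence:
    """A protein sequence with optional full-length numbering offset.

    ``numbering_offset`` is the 1-based index of the first residue in the
    full-length protein, so hits report coordinates in author numbering.
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = set(self.residues) - AMINO_ACIDS - {"X", "-"}
        if bad:
            raise ValueError(f"sequence {self.id}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


class ResidueClassTable:
    """Resolves template class symbols to residue sets.

    Built-in classes: ``X`` (any residue), ``Φa`` (aliphatic: A,V,L,I,M),
    ``Φs`` (short hydrophilic: S,T). Single residue letters are singletons
    and ``A/B`` alternations resolve to the listed set. ASCII aliases
    ``Pa``/``Ps`` are accepted for the phi classes.
    """

    _BUILTIN = {
        "X": frozenset(AMINO_ACIDS),
        "Φa": frozenset("AVLIM"),
        "Φs": frozenset("ST"),
        "Pa": frozenset("AVLIM"),
        "Ps": frozenset("ST"),
    }

    def __init__(self, extra: Mapping[str, Iterable[str]] | None = None):
        self.classes: dict[str, frozenset[str]] = dict(self._BUILTIN)
        for sym, residues in (extra or {}).items():
            resset = frozenset(str(r).upper() for r in residues)
            if not resset or not resset <= AMINO_ACIDS:
                raise ValueError(f"class {sym!r}: residue set must be a non-empty "
                                 f"subset of the 20-letter alphabet")
            self.classes[sym] = resset

    def resolve(self, symbol: str) -> frozenset[str]:
        if symbol in self.classes:
            return self.classes[symbol]
        if len(symbol) == 1 and symbol.upper() in AMINO_ACIDS:
            return frozenset(symbol.upper())
        if "/" in symbol:
            parts = [p.strip().upper() for p in symbol.split("/")]
            if all(len(p) == 1 and p in AMINO_ACIDS for p in parts) and parts:
                return frozenset(parts)
        raise ValueError(f"unknown residue-class symbol {symbol!r}")


@dataclasses.dataclass(frozen=True)
class MotifTemplate:
    name: str
    positions: tuple[frozenset[str], ...]
    symbols: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.positions)


@dataclasses.dataclass
class MotifHit:
    """A scored window; ``start``/``end`` are 1-based inclusive in
    full-length protein numbering."""

    sequence_id: str
    start: int
    end: int
    matched: str
    template: str
    score: float
    n_strict_mismatches: int


def parse_template(spec: str, table: ResidueClassTable | None = None,
                   name: str | None = None) -> MotifTemplate:
    """Parse a dash-delimited template such as ``"W-Φs-D-X-P"``."""
    table = table or ResidueClassTable()
    tokens = [t.strip() for t in spec.split("-")] if spec.strip() else []
    if not tokens or any(not t for t in tokens):
        raise ValueError(f"template spec {spec!r}: empty or has empty tokens")
    positions = tuple(table.resolve(t) for t in tokens)
    return MotifTemplate(name=name or spec, positions=positions, symbols=tuple(tokens))


def default_templates(table: ResidueClassTable | None = None) -> list[MotifTemplate]:
    """The three phage-display-derived internal-motif templates."""
    return [parse_template(s, table) for s in
            ("X-Y-G-W-Φa-D/G", "X-W-Φa-D-G-P", "W-Φs-D-X-P")]


DEFAULT_TEMPLATES = default_templates()


def _position_score(residue: str, allowed: frozenset[str], s_cons: float,
                    groups: Sequence[frozenset[str]]) -> float:
    if residue in allowed:
        return 1.0
    if residue == "X":
        return 0.0
    for g in groups:
        if residue in g and allowed & g:
            return s_cons
    return 0.0


def scan(seq: ProteinSequence, templates: Sequence[MotifTemplate] | None = None,
         min_score: float = 0.8, max_strict_mismatches: int = 1,
         s_cons: float = 0.5,
         groups: Sequence[frozenset[str]] = CONSERVATIVE_GROUPS) -> list[MotifHit]:
    """Scan a sequence with degenerate templates.

    Each window position scores 1 for class membership, ``s_cons`` for a
    conservative substitution (same fixed substitution group as an allowed
    residue) and 0 otherwise; the window score is the mean. Windows pass if
    score >= ``min_score`` and the number of zero-scoring positions is
    <= ``max_strict_mismatches``. Hits are sorted by descending score, then
    ascending start, then template order as supplied. Overlapping hits from
    different templates are all reported.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must lie in [0, 1]")
    if templates is None:
        templates = DEFAULT_TEMPLATES
    residues = seq.residues
    hits: list[tuple[float, int, int, MotifHit]] = []
    for t_order, tpl in enumerate(templates):
        L = len(tpl)
        for start0 in range(len(residues) - L + 1):
            window = residues[start0:start0 + L]
            scores = [_position_score(r, allowed, s_cons, groups)
                      for r, allowed in zip(window, tpl.positions)]
            strict = sum(1 for s in scores if s == 0.0)
            score = float(np.mean(scores))
            if score >= min_score and strict <= max_strict_mismatches:
                start = start0 + seq.numbering_offset
                hit = MotifHit(sequence_id=seq.id, start=start, end=start + L - 1,
                               matched=window, template=tpl.name, score=score,
                               n_strict_mismatches=strict)
                hits.append((-score, start, t_order, hit))
    hits.sort(key=lambda x: x[:3])
    return [h for *_, h in hits]


class PdzPositionMap(dict):
    """Map from 1-based peptide residue index to signed P index."""

    @property
    def p0_index(self) -> int:
        return next(i for i, p in self.items() if p == 0)

    def residue_at(self, peptide: str, p: int) -> str:
        idx = next(i for i, q in self.items() if q == p)
        return peptide[idx - 1]


def assign_pdz_positions(peptide: str, anchor: str = "aspartate-carboxylate-mimic",
                         anchor_index: int | None = None) -> PdzPositionMap:
    """Assign P positions relative to the carboxylate-mimicking anchor.

    Under the default rule the anchor is the peptide's single aspartate
    (whose side chain mimics a free C-terminal carboxylate); it becomes P0,
    residues C-terminal of it P1, P2, ... and N-terminal P-1, P-2, ...
    Ambiguity (multiple Asp) must be resolved with an explicit 1-based
    ``anchor_index``.
    """
    peptide = peptide.upper()
    if anchor != "aspartate-carboxylate-mimic":
        raise ValueError(f"unknown anchor rule {anchor!r}")
    if anchor_index is None:
        asp = [i + 1 for i, r in enumerate(peptide) if r == "D"]
        if not asp:
            raise ValueError("no aspartate anchor in peptide")
        if len(asp) > 1:
            raise ValueError(
                f"ambiguous anchor: aspartates at positions {asp}; "
                f"supply anchor_index explicitly")
        anchor_index = asp[0]
    if not 1 <= anchor_index <= len(peptide):
        raise ValueError("anchor_index out of range")
    return PdzPositionMap({i: i - anchor_index for i in range(1, len(peptide) + 1)})


def conservation_profile(aligned: Sequence[ProteinSequence]) -> np.ndarray:
    """Per-column identity fraction of a pre-aligned sequence set.

    Column value = count of the most frequent non-gap residue divided by
    the number of non-gap residues in that column; gap-only columns are NaN.
    """
    if len(aligned) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in aligned}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences must share one length; got {sorted(lengths)}")
    ncol = lengths.pop()
    out = np.empty(ncol)
    for c in range(ncol):
        col = [s.residues[c] for s in aligned if s.residues[c] != "-"]
        if not col:
            out[c] = np.nan
            continue
        _, counts = np.unique(col, return_counts=True)
        out[c] = counts.max() / len(col)
    return out
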