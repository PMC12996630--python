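"""Motif patterns and the binary motif-occurrence feature block.

Two routes produce the block: scanning PROSITE-style patterns against the
sequences directly, or consuming an external tabular hit file
(``sample_id<TAB>motif_id<TAB>evalue``, e.g. exported from a MAST run) and
thresholding on E-value. Motif discovery itself is external; this module only
consumes patterns or hits. Absent motifs are encoded as 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .seqio import ALPHABET, PeptideSet


class MotifPatternError(ValueError):
    """Raised when a motif pattern cannot be parsed."""


class MotifHitError(ValueError):
    """Raised when a hit table references unknown samples or motifs."""


# one PROSITE element: letter, x, [class], {negated class}, optional (n) or (n,m)
_ELEMENT_RE = re.compile(
    r"^(?P<core>[A-Za-z]|x|\[[A-Za-z]+\]|\{[A-Za-z]+\})"
    r"(?:\((?P<lo>\d+)(?:,(?P<hi>\d+))?\))?$"
)
_ALPHABET_SET = frozenset(ALPHABET)


def _parse_elements(pattern: str) -> list[tuple[str, int, int]]:
    """Parse a PROSITE-style pattern into (letter-choices, min, max) elements.

    Supported syntax: residue letters, ``x`` wildcards, ``[...]`` classes,
    ``{...}`` negated classes, ``(n)`` / ``(n,m)`` repeats, ``<`` / ``>``
    anchors (handled by the caller), ``-`` separators, trailing ``.``.
    """
    pat = pattern.strip().rstrip(".")
    elements: list[tuple[str, int, int]] = []
    for tok in pat.split("-"):
        tok = tok.strip()
        if not tok:
            raise MotifPatternError(f"empty element in pattern {pattern!r}")
        m = _ELEMENT_RE.match(tok)
        if m is None:
            raise MotifPatternError(f"cannot parse element {tok!r} in {pattern!r}")
        core = m.group("core")
        if core == "x":
            choices = ALPHABET
        elif core.startswith("["):
            choices = core[1:-1].upper()
        elif core.startswith("{"):
            choices = "".join(sorted(_ALPHABET_SET - set(core[1:-1].upper())))
        else:
            choices = core.upper()
        bad = set(choices) - _ALPHABET_SET
        if bad:
            raise MotifPatternError(
                f"non-amino-acid letter(s) {sorted(bad)} in element {tok!r}"
            )
        lo = int(m.group("lo")) if m.group("lo") else 1
        hi = int(m.group("hi")) if m.group("hi") else lo
        if lo < 1 or hi < lo:
            raise MotifPatternError(f"bad repeat count in element {tok!r}")
        elements.append((choices, lo, hi))
    return elements


@dataclass(frozen=True)
class Motif:
    """A PROSITE-style sequence pattern with a compiled matcher."""

    id: str
    pattern: str
    _elements: tuple = field(repr=False, compare=False, default=())
    _regex: re.Pattern = field(repr=False, compare=False, default=None)

    @classmethod
    def compile(cls, id: str, pattern: str) -> "Motif":
        pat = pattern.strip()
        anchored_start = pat.startswith("<")
        anchored_end = pat.endswith(">")
        core = pat.lstrip("<").rstrip(">")
        elements = _parse_elements(core)
        regex = "".join(
            (f"[{choices}]" if len(choices) > 1 else choices)
            + ("" if (lo, hi) == (1, 1) else
               (f"{{{lo}}}" if lo == hi else f"{{{lo},{hi}}}"))
            for choices, lo, hi in elements
        )
        if anchored_start:
            regex = "^" + regex
        if anchored_end:
            regex = regex + "$"
        return cls(id, pattern, tuple(elements), re.compile(regex))

    def matches(self, sequence: str) -> bool:
        return self._regex.search(sequence.upper()) is not None

    def sample(self, rng: np.random.Generator) -> str:
        """A random concrete sequence matching the pattern."""
        out = []
        for choices, lo, hi in self._elements:
            n = int(rng.integers(lo, hi + 1))
            out.extend(choices[i] for i in rng.integers(0, len(choices), size=n))
        return "".join(out)


def parse_motifs(path) -> list[Motif]:
    """Read a motif pattern file: one ``id<TAB>pattern`` per line, ``#`` comments."""
    motifs: list[Motif] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                mid, pattern = line.split("\t")
            except ValueError as exc:
                raise MotifPatternError(
                    f"{path}: line {lineno}: expected 'id<TAB>pattern'"
                ) from exc
            if mid in seen:
                raise MotifPatternError(f"{path}: line {lineno}: duplicate id {mid!r}")
            seen.add(mid)
            try:
                motifs.append(Motif.compile(mid, pattern))
            except MotifPatternError as exc:
                raise MotifPatternError(f"{path}: line {lineno}: {exc}") from exc
    return motifs


def scan_sequence(sequence: str, motif: Motif) -> bool:
    """True iff the motif matches anywhere in the sequence (case-insensitive)."""
    return motif.matches(sequence)


@dataclass
class MotifVectorBlock:
    """Binary samples x motifs occurrence matrix."""

    sample_ids: list[str]
    motif_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.sample_ids), len(self.motif_ids)):
            raise ValueError("motif block shape inconsistent with id lists")
        if self.matrix.size and not np.isin(self.matrix, (0.0, 1.0)).all():
            raise ValueError("motif block entries must be 0/1")

    def align_to(self, sample_ids: list[str]) -> np.ndarray:
        """Rows reordered to the given sample ids."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise MotifHitError(f"motif block missing sample(s): {', '.join(missing)}")
        return self.matrix[[pos[s] for s in sample_ids], :]


def motif_block_from_scan(pset: PeptideSet, motifs: list[Motif]) -> MotifVectorBlock:
    """Scan every peptide against every motif pattern; 1 = match anywhere."""
    matrix = np.zeros((len(pset), len(motifs)))
    for i, rec in enumerate(pset):
        for j, motif in enumerate(motifs):
            if scan_sequence(rec.sequence, motif):
                matrix[i, j] = 1.0
    return MotifVectorBlock(pset.ids, [m.id for m in motifs], matrix)


@dataclass(frozen=True)
class MotifHit:
    sample_id: str
    motif_id: str
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise MotifHitError(
                f"hit ({self.sample_id}, {self.motif_id}): evalue must be > 0"
            )


def read_hits(path) -> list[MotifHit]:
    """Read a MAST-style hit table: ``sample_id<TAB>motif_id<TAB>evalue``."""
    hits: list[MotifHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise MotifHitError(
                    f"{path}: line {lineno}: expected sample_id<TAB>motif_id<TAB>evalue"
                )
            hits.append(MotifHit(parts[0], parts[1], float(parts[2])))
    return hits


def motif_block_from_hits(
    pset: PeptideSet,
    motif_ids: list[str],
    hits: list[MotifHit],
    evalue_threshold: float,
    direction: str = "le",
) -> MotifVectorBlock:
    """Binary block from an external hit table.

    With the default ``direction='le'`` a motif is present when some hit has
    ``evalue <= threshold`` (the universal significance convention; smaller
    E-value = more significant). ``direction='ge'`` inverts the comparison.
    Duplicated (sample, motif) rows keep their minimum E-value. Samples or
    motifs with no hits stay 0.
    """
    if direction not in ("le", "ge"):
        raise ValueError("direction must be 'le' or 'ge'")
    sample_pos = {s: i for i, s in enumerate(pset.ids)}
    motif_pos = {m: j for j, m in enumerate(motif_ids)}
    unknown = sorted(
        {h.sample_id for h in hits if h.sample_id not in sample_pos}
        | {h.motif_id for h in hits if h.motif_id not in motif_pos}
    )
    if unknown:
        raise MotifHitError("hit(s) reference unknown ids: " + ", ".join(unknown))

    best: dict[tuple[int, int], float] = {}
    for h in hits:
        key = (sample_pos[h.sample_id], motif_pos[h.motif_id])
        best[key] = min(best.get(key, np.inf), h.evalue)

    matrix = np.zeros((len(pset), len(motif_ids)))
    for (i, j), ev in best.items():
        significant = ev <= evalue_threshold if direction == "le" else ev >= evalue_threshold
        if significant:
            matrix[i, j] = 1.0
    return MotifVectorBlock(pset.ids, list(motif_ids), matrix)
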