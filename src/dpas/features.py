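"""Sequence descriptors and feature-matrix assembly.

The descriptor panel: amino-acid composition (AAC, 20), reduced-alphabet
grouped composition (GRP, 11), mean residue volume and mean Hopp-Woods
hydrophilicity (one scalar each), five physicochemical-class fractions
(PCP, 5), whole-sequence Shannon entropy of the residue composition (SER, 1),
repetitive-residue information (RRI, 20) and dipeptide composition (DPC, 400)
— 458 numeric columns, plus an optional binary motif block appended on the
right. Column order is fixed so fitted scalers/PCA/models are portable across
runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy

from .seqio import ALPHABET, PeptideSet, chunk_records

_LETTER_INDEX = {a: i for i, a in enumerate(ALPHABET)}
DIPEPTIDES = ["".join(p) for p in itertools.product(ALPHABET, repeat=2)]

AAC_NAMES = [f"AAC_{a}" for a in ALPHABET]
RRI_NAMES = [f"RRI_{a}" for a in ALPHABET]
DPC_NAMES = [f"DPC_{d}" for d in DIPEPTIDES]
PCP_CLASS_ORDER = ["HB", "HL", "NT", "PC", "NC"]


class FeatureError(ValueError):
    """Raised for invalid descriptor inputs (empty sequence, bad scheme...)."""


# ---------------------------------------------------------------------------
# scales and grouping schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AminoAcidScale:
    """A named mapping from each of the 20 amino acids to a real value."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(ALPHABET):
            missing = sorted(set(ALPHABET) - set(self.values))
            extra = sorted(set(self.values) - set(ALPHABET))
            raise FeatureError(
                f"scale {self.name!r} must map exactly the 20 amino acids"
                + (f"; missing {missing}" if missing else "")
                + (f"; unexpected {extra}" if extra else "")
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.values[a] for a in ALPHABET], dtype=float)

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "AminoAcidScale":
        values: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                letter, val = line.split("\t")
                values[letter.upper()] = float(val)
        return cls(name or str(path), values)


@dataclass(frozen=True)
class GroupingScheme:
    """An ordered partition of the 20 amino acids into labelled groups."""

    name: str
    groups: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        letters = [a for _, members in self.groups for a in members]
        if sorted(letters) != sorted(ALPHABET):
            raise FeatureError(
                f"grouping {self.name!r} must partition the 20-letter alphabet "
                f"(got letters {''.join(sorted(letters))!r})"
            )
        labels = [label for label, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise FeatureError(f"grouping {self.name!r} has duplicate group labels")

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.groups]

    def group_of(self) -> dict[str, int]:
        """letter -> group index"""
        return {
            a: gi for gi, (_, members) in enumerate(self.groups) for a in members
        }

    @classmethod
    def from_pairs(cls, name: str, pairs: list[tuple[str, str]]) -> "GroupingScheme":
        return cls(
            name,
            tuple((label, frozenset(members.upper())) for label, members in pairs),
        )

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "GroupingScheme":
        pairs: list[tuple[str, str]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                label, members = line.split("\t")
                pairs.append((label, members))
        return cls.from_pairs(name or str(path), pairs)


def _data_path(fname: str):
    return resources.files("dpas.data").joinpath(fname)


def default_volume_scale() -> AminoAcidScale:
    """Residue volumes (A^3), Zamyatnin (1972) tabulation."""
    return AminoAcidScale.from_tsv(_data_path("volume_zamyatnin1972.tsv"), "volume")


def default_hydrophobicity_scale() -> AminoAcidScale:
    """Hopp & Woods (1981) hydrophilicity values."""
    return AminoAcidScale.from_tsv(
        _data_path("hydrophobicity_hoppwoods1981.tsv"), "hydrophobicity"
    )


def default_grouping_scheme() -> GroupingScheme:
    """Shipped 11-group reduced alphabet (see the data file header)."""
    return GroupingScheme.from_tsv(_data_path("grouping_sezerman11.tsv"), "grp11")


def default_pcp_scheme() -> GroupingScheme:
    """Shipped 5-class physicochemical partition (HB/HL/NT/PC/NC)."""
    scheme = GroupingScheme.from_tsv(_data_path("pcp_classes5.tsv"), "pcp5")
    if scheme.labels != PCP_CLASS_ORDER:
        raise FeatureError("pcp scheme must define classes HB, HL, NT, PC, NC in order")
    return scheme


# ---------------------------------------------------------------------------
# per-sequence descriptors
# ---------------------------------------------------------------------------

def _check_sequence(sequence: str, min_len: int = 1) -> str:
    if len(sequence) < min_len:
        raise FeatureError(
            f"sequence must have length >= {min_len}, got {len(sequence)}"
        )
    return sequence.upper()


def _counts(sequence: str) -> np.ndarray:
    counts = np.zeros(20)
    for a in sequence:
        counts[_LETTER_INDEX[a]] += 1
    return counts


def aac(sequence: str) -> np.ndarray:
    """Amino-acid composition: per-letter frequency / length, fixed order A..Y."""
    seq = _check_sequence(sequence)
    return _counts(seq) / len(seq)


def grouped_aac(sequence: str, scheme: GroupingScheme) -> np.ndarray:
    """Composition over a reduced alphabet: group-wise sums of :func:`aac`."""
    comp = aac(sequence)
    out = np.zeros(len(scheme.groups))
    for letter, gi in scheme.group_of().items():
        out[gi] += comp[_LETTER_INDEX[letter]]
    return out


def scale_mean(sequence: str, scale: AminoAcidScale) -> float:
    """Mean per-residue value of an amino-acid scale over the sequence."""
    seq = _check_sequence(sequence)
    vals = scale.as_array()
    return float(np.mean([vals[_LETTER_INDEX[a]] for a in seq]))


def pcp_composition(sequence: str, classes: GroupingScheme | None = None) -> np.ndarray:
    """Fractions of residues falling in each of 5 physicochemical classes."""
    classes = classes or default_pcp_scheme()
    if len(classes.groups) != 5:
        raise FeatureError("physicochemical composition expects exactly 5 classes")
    return grouped_aac(sequence, classes)


def shannon_entropy(sequence: str) -> float:
    """Shannon entropy (bits) of the whole-sequence residue composition.

    0 for homopolymers, log2(20) for a sequence using all 20 letters equally.
    """
    return float(_scipy_entropy(aac(sequence), base=2))


def rri(sequence: str) -> np.ndarray:
    """Repetitive-residue information: count/length for letters occurring
    at least twice, 0 for letters occurring once or not at all."""
    seq = _check_sequence(sequence)
    counts = _counts(seq)
    out = counts / len(seq)
    out[counts < 2] = 0.0
    return out


def dpc(sequence: str) -> np.ndarray:
    """Dipeptide composition: adjacent-pair frequencies over the 400 pairs,
    lexicographic order AA..YY, normalized by (length - 1)."""
    seq = _check_sequence(sequence, min_len=2)
    out = np.zeros(400)
    for a, b in zip(seq, seq[1:]):
        out[_LETTER_INDEX[a] * 20 + _LETTER_INDEX[b]] += 1
    return out / (len(seq) - 1)


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Named samples x named features, finite values."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise FeatureError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.feature_names)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FeatureError("sample ids must be unique")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise FeatureError("feature names must be unique")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise FeatureError("feature matrix contains NaN/inf")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.feature_names,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls.from_frame(df)

    def select(self, feature_names: list[str]) -> "FeatureMatrix":
        missing = [f for f in feature_names if f not in self.feature_names]
        if missing:
            raise FeatureError(f"unknown feature(s): {', '.join(missing)}")
        idx = [self.feature_names.index(f) for f in feature_names]
        return FeatureMatrix(self.sample_ids, feature_names, self.values[:, idx])


@dataclass
class FeatureConfig:
    """Which descriptor blocks to compute and with which backing tables."""

    aac: bool = True
    grouped: bool = True
    volume: bool = True
    hydrophobicity: bool = True
    pcp: bool = True
    entropy: bool = True
    rri: bool = True
    dpc: bool = True
    grouping_scheme: GroupingScheme = field(default_factory=default_grouping_scheme)
    pcp_scheme: GroupingScheme = field(default_factory=default_pcp_scheme)
    volume_scale: AminoAcidScale = field(default_factory=default_volume_scale)
    hydrophobicity_scale: AminoAcidScale = field(
        default_factory=default_hydrophobicity_scale
    )

    def feature_names(self) -> list[str]:
        names: list[str] = []
        if self.aac:
            names += AAC_NAMES
        if self.grouped:
            names += [f"GRP_{g}" for g in self.grouping_scheme.labels]
        if self.volume:
            names.append("Volume_Measure")
        if self.hydrophobicity:
            names.append("Hydrophobicity_Measure")
        if self.pcp:
            names += [f"PCP_{c}" for c in self.pcp_scheme.labels]
        if self.entropy:
            names.append("SER")
        if self.rri:
            names += RRI_NAMES
        if self.dpc:
            names += DPC_NAMES
        return names


def _featurize_one(seq: str, config: FeatureConfig) -> np.ndarray:
    parts: list[np.ndarray] = []
    if config.aac:
        parts.append(aac(seq))
    if config.grouped:
        parts.append(grouped_aac(seq, config.grouping_scheme))
    if config.volume:
        parts.append(np.array([scale_mean(seq, config.volume_scale)]))
    if config.hydrophobicity:
        parts.append(np.array([scale_mean(seq, config.hydrophobicity_scale)]))
    if config.pcp:
        parts.append(pcp_composition(seq, config.pcp_scheme))
    if config.entropy:
        parts.append(np.array([shannon_entropy(seq)]))
    if config.rri:
        parts.append(rri(seq))
    if config.dpc:
        parts.append(dpc(seq))
    return np.concatenate(parts) if parts else np.zeros(0)


def assemble_feature_matrix(
    pset: PeptideSet,
    config: FeatureConfig | None = None,
    motif_block=None,
    n_chunks: int = 1,
    skip_invalid: bool = False,
) -> FeatureMatrix:
    """Compute the full descriptor matrix for a peptide set.

    ``motif_block`` (a :class:`dpas.motifs.MotifVectorBlock`) is appended as
    MOTIF_* columns. ``n_chunks`` splits the work into contiguous chunks whose
    concatenation is bit-identical to a single pass (each row depends only on
    its own sequence). With ``skip_invalid``, peptides too short for an enabled
    block (a 1-residue peptide when DPC is on) are dropped with a warning
    instead of raising.
    """
    import logging

    config = config or FeatureConfig()
    names = config.feature_names()

    rows: list[np.ndarray] = []
    kept_ids: list[str] = []
    for chunk in chunk_records(pset, n_chunks):
        for rec in chunk:
            try:
                rows.append(_featurize_one(rec.sequence, config))
                kept_ids.append(rec.id)
            except FeatureError as exc:
                if not skip_invalid:
                    raise FeatureError(f"record {rec.id!r}: {exc}") from exc
                logging.getLogger(__name__).warning(
                    "skipping record %r: %s", rec.id, exc
                )

    values = np.vstack(rows) if rows else np.zeros((0, len(names)))
    fm = FeatureMatrix(kept_ids, names, values)

    if motif_block is not None and len(motif_block.motif_ids) > 0:
        block = motif_block.align_to(kept_ids)
        fm = FeatureMatrix(
            kept_ids,
            names + [f"MOTIF_{m}" for m in motif_block.motif_ids],
            np.hstack([fm.values, block]),
        )
    return fm
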