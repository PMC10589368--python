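"""Reading, writing and validating aligned gRNA–target sequence-pair datasets.

A sample is a pre-aligned pair of 23-symbol sequences over the alphabet
``{A, C, G, T, -}``: positions 1–20 hold the protospacer alignment, positions
21–23 the PAM.  A ``-`` marks a bulge — an unpaired base on the RNA side
(``-`` in the guide) or the DNA side (``-`` in the target).  Each pair carries
a binary activity label (1 = validated off-target cleavage) and, for
cleavage-enrichment assays such as CIRCLE-seq, an optional read count.

Files are plain delimited text (CSV or TSV).  Because published off-target
tables do not share a column naming convention, :func:`read_pairs_table`
accepts a *dialect* mapping from the canonical field names
(``guide``, ``target``, ``label``, ``reads``) to whatever headers the file
uses; a set of common aliases is recognised out of the box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

ALPHABET = frozenset("ACGT-")
PAIR_LENGTH = 23

#: Header aliases tried (case-insensitively) when no dialect is given.
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "guide": ("guide", "sgrna", "grna", "on_seq", "crrna", "guide_seq"),
    "target": ("target", "dna", "off_seq", "target_seq", "offtarget"),
    "label": ("label", "class", "active", "y"),
    "reads": ("reads", "read", "count", "reads_count"),
}


class ValidationError(ValueError):
    """A sequence pair or table row violates the dataset contract."""


class UndefinedRatioError(ValueError):
    """Imbalance ratio requested for a dataset missing a class."""


@dataclass(frozen=True)
class GuideTargetPair:
    """One aligned gRNA–target pair with its activity annotation.

    Parameters
    ----------
    guide, target : str
        23-symbol aligned sequences over ``{A, C, G, T, -}``.  A ``-`` in
        *guide* is an RNA bulge (unpaired DNA base), a ``-`` in *target* a
        DNA bulge (unpaired gRNA base).  Never ``-`` in both at one position.
    label : int
        1 if the pair is an experimentally active off-target, else 0.
    reads : int, optional
        Assay read count supporting the call, when the source provides one.
    source : str, optional
        Free-text tag naming the dataset of origin.
    """

    guide: str
    target: str
    label: int
    reads: int | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "guide", self.guide.upper())
        object.__setattr__(self, "target", self.target.upper())
        self.validate()

    def validate(self) -> None:
        for name, seq in (("guide", self.guide), ("target", self.target)):
            if len(seq) != PAIR_LENGTH:
                raise ValidationError(
                    f"{name} has length {len(seq)}, expected {PAIR_LENGTH}: {seq!r}"
                )
            bad = set(seq) - ALPHABET
            if bad:
                raise ValidationError(
                    f"{name} contains invalid symbol(s) {sorted(bad)}: {seq!r}"
                )
        for i, (g, t) in enumerate(zip(self.guide, self.target)):
            if g == "-" and t == "-":
                raise ValidationError(
                    f"position {i + 1} is '-' in both guide and target"
                )
        if self.label not in (0, 1):
            raise ValidationError(f"label must be 0 or 1, got {self.label!r}")
        if self.reads is not None and self.reads < 0:
            raise ValidationError(f"reads must be nonnegative, got {self.reads}")

    @property
    def has_bulge(self) -> bool:
        return "-" in self.guide or "-" in self.target

    def mismatch_count(self) -> int:
        """Number of positions where both strands carry a base and they differ."""
        return sum(
            1
            for g, t in zip(self.guide, self.target)
            if g != "-" and t != "-" and g != t
        )


@dataclass
class Dataset:
    """An ordered collection of :class:`GuideTargetPair` with a name."""

    name: str
    pairs: list[GuideTargetPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[GuideTargetPair]:
        return iter(self.pairs)

    def __getitem__(self, idx: int) -> GuideTargetPair:
        return self.pairs[idx]

    def labels(self) -> list[int]:
        return [p.label for p in self.pairs]

    def subset(self, indices: Sequence[int], name: str | None = None) -> "Dataset":
        return Dataset(name or self.name, [self.pairs[i] for i in indices])

    @staticmethod
    def concatenate(datasets: Iterable["Dataset"], name: str = "pooled") -> "Dataset":
        pairs: list[GuideTargetPair] = []
        for ds in datasets:
            pairs.extend(ds.pairs)
        return Dataset(name, pairs)


def _resolve_columns(
    columns: Sequence[str], dialect: Mapping[str, str] | None
) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved: dict[str, str] = {}
    if dialect:
        for canon, actual in dialect.items():
            if actual.lower() not in lower:
                raise ValidationError(f"mapped column {actual!r} not present in file")
            resolved[canon] = lower[actual.lower()]
    for canon, aliases in DEFAULT_ALIASES.items():
        if canon in resolved:
            continue
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    for required in ("guide", "target", "label"):
        if required not in resolved:
            raise ValidationError(
                f"could not locate a {required!r} column among {list(columns)}"
            )
    return resolved


def read_pairs_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    name: str | None = None,
) -> Dataset:
    """Read a delimited table of aligned pairs into a validated :class:`Dataset`.

    The delimiter is sniffed from the extension (``.tsv`` → tab, else comma).
    Row order is preserved.  Any row failing validation aborts the read with a
    :class:`ValidationError` naming the offending row and field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = _resolve_columns(list(frame.columns), dialect)

    pairs: list[GuideTargetPair] = []
    errors: list[str] = []
    for row_idx, row in enumerate(frame.itertuples(index=False), start=2):
        rec = dict(zip(frame.columns, row))
        try:
            reads_raw = rec.get(cols["reads"], "") if "reads" in cols else ""
            reads = int(float(reads_raw)) if reads_raw not in ("", "NA") else None
            pairs.append(
                GuideTargetPair(
                    guide=rec[cols["guide"]],
                    target=rec[cols["target"]],
                    label=int(float(rec[cols["label"]])),
                    reads=reads,
                    source=name,
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {row_idx}: {exc}")
    if errors:
        raise ValidationError(
            f"{len(errors)} invalid row(s) in {path.name}:\n" + "\n".join(errors[:20])
        )
    return Dataset(name or path.stem, pairs)


def write_pairs_table(dataset: Dataset, path: str | Path) -> Path:
    """Write a dataset back to delimited text (inverse of :func:`read_pairs_table`)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    frame = pd.DataFrame(
        {
            "guide": [p.guide for p in dataset.pairs],
            "target": [p.target for p in dataset.pairs],
            "label": [p.label for p in dataset.pairs],
            "reads": ["" if p.reads is None else p.reads for p in dataset.pairs],
        }
    )
    frame.to_csv(path, sep=sep, index=False)
    return path


def imbalance_ratio_from_counts(negatives: int, positives: int) -> int:
    """Floor of negatives per positive, the convention used to report class skew."""
    if positives == 0 or negatives == 0:
        raise UndefinedRatioError(
            f"imbalance ratio undefined: {positives} positives, {negatives} negatives"
        )
    return negatives // positives


def imbalance_ratio(dataset: Dataset) -> int:
    """Class skew of a dataset as floor(negatives / positives).

    Raises :class:`UndefinedRatioError` if either class is absent.
    """
    pos = sum(dataset.labels())
    return imbalance_ratio_from_counts(len(dataset) - pos, pos)


@dataclass(frozen=True)
class DatasetSummary:
    name: str
    total: int
    positives: int
    negatives: int
    indel_pairs: int
    ratio: int | None  # None when one class is absent

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "total": self.total,
            "positives": self.positives,
            "negatives": self.negatives,
            "indel_pairs": self.indel_pairs,
            "ratio": self.ratio,
        }


def dataset_summary(dataset: Dataset) -> DatasetSummary:
    """Per-dataset sample profile: totals, class counts, bulge pairs, skew."""
    pos = sum(dataset.labels())
    neg = len(dataset) - pos
    indels = sum(1 for p in dataset if p.has_bulge)
    try:
        ratio: int | None = imbalance_ratio(dataset)
    except UndefinedRatioError:
        ratio = None
    return DatasetSummary(dataset.name, len(dataset), pos, neg, indels, ratio)
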