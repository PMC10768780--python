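"""Core sample containers for fixed-length Nm-site windows.

A *sample* is a 41-nt RNA window centered (0-based index 20) on a candidate
2'-O-methylated nucleotide, with 20-nt flanks on either side.  Datasets are
typed by the central base: ``A``, ``C``, ``G``, ``U`` for nucleotide-specific
collections, or ``N`` for the merged generic collection whose central base is
unconstrained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

WINDOW_LENGTH = 41
CENTER_INDEX = 20
ALPHABET = "ACGU"
SITE_TYPES = ("A", "C", "G", "U", "N")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class SequenceError(ValueError):
    """Raised when a sequence violates the window invariants."""


def normalize_sequence(seq: str) -> str:
    """Uppercase a sequence and map DNA-style T to U.

    Any residual character outside {A, C, G, U} raises :class:`SequenceError`;
    descriptors and embeddings are defined only over the 4-letter RNA alphabet.
    """
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - set(ALPHABET)
    if bad:
        raise SequenceError(f"invalid characters {sorted(bad)} in sequence {seq!r}")
    return s


def reverse_complement(seq: str) -> str:
    """RNA reverse complement (A<->U, C<->G, reversed)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Sample:
    """One candidate-site window.

    Attributes
    ----------
    id : str
        Record identifier (unique within a dataset).
    seq : str
        Normalized 41-nt sequence over {A, C, G, U}.
    label : int
        1 for a 2'-O-methylated (Nm) site, 0 for a non-site.
    site_type : str
        Central-base type; one of A/C/G/U/N.
    """

    id: str
    seq: str
    label: int
    site_type: str = "N"

    def validate(self, length: int = WINDOW_LENGTH) -> None:
        if self.site_type not in SITE_TYPES:
            raise SequenceError(f"{self.id}: unknown site type {self.site_type!r}")
        if len(self.seq) != length:
            raise SequenceError(
                f"{self.id}: sequence length {len(self.seq)} != {length}"
            )
        if set(self.seq) - set(ALPHABET):
            raise SequenceError(f"{self.id}: sequence not over A/C/G/U")
        if self.label not in (0, 1):
            raise SequenceError(f"{self.id}: label must be 0 or 1")
        if self.site_type != "N" and self.seq[CENTER_INDEX] != self.site_type:
            raise SequenceError(
                f"{self.id}: central base {self.seq[CENTER_INDEX]} does not match "
                f"site type {self.site_type}"
            )


@dataclass
class SiteDataset:
    """An ordered, id-unique collection of :class:`Sample` of one site type."""

    samples: list[Sample] = field(default_factory=list)
    site_type: str = "N"
    name: str = "dataset"

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise SequenceError(f"duplicate sample id {dup!r} in dataset {self.name}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[Sample]:
        return iter(self.samples)

    def __getitem__(self, i: int) -> Sample:
        return self.samples[i]

    @property
    def labels(self) -> list[int]:
        return [s.label for s in self.samples]

    @property
    def sequences(self) -> list[str]:
        return [s.seq for s in self.samples]

    def validate(self) -> None:
        for s in self.samples:
            s.validate()
            if self.site_type != "N" and s.site_type != self.site_type:
                raise SequenceError(
                    f"{s.id}: sample site type {s.site_type} inconsistent with "
                    f"dataset site type {self.site_type}"
                )

    def subset(self, indices: Iterable[int], name: str | None = None) -> "SiteDataset":
        return SiteDataset(
            samples=[self.samples[i] for i in indices],
            site_type=self.site_type,
            name=name or self.name,
        )

    def class_counts(self) -> tuple[int, int]:
        """(n_negative, n_positive)."""
        pos = sum(s.label for s in self.samples)
        return len(self.samples) - pos, pos
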