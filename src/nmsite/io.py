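"""FASTA / CSV input-output, dataset merging and deduplication.

Label conventions (both documented dialects are supported):

* **paired files** — one FASTA of positives, one of negatives, read with
  ``label=1`` / ``label=0``;
* **header token** — a ``label=0`` / ``label=1`` token anywhere in the FASTA
  description line, read with ``label=None``.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .samples import (
    CENTER_INDEX,
    WINDOW_LENGTH,
    Sample,
    SequenceError,
    SiteDataset,
    normalize_sequence,
)

logger = logging.getLogger("nmsite")

_LABEL_RE = re.compile(r"\blabel=([01])\b")


@dataclass(frozen=True)
class PredictionRecord:
    """One per-sequence prediction: probability of an Nm site plus hard call."""

    id: str
    seq: str
    probability: float
    predicted_label: int
    model_name: str = "N2OM"

    def validate(self, threshold: float = 0.5) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"{self.id}: probability {self.probability} outside [0,1]")
        expected = int(self.probability >= threshold)
        if self.predicted_label != expected:
            raise ValueError(
                f"{self.id}: label {self.predicted_label} inconsistent with "
                f"probability {self.probability} at threshold {threshold}"
            )


def read_fasta(
    path: str | Path,
    site_type: str = "N",
    label: int | None = None,
    strict: bool = True,
    length: int = WINDOW_LENGTH,
) -> SiteDataset:
    """Read fixed-length site windows from a FASTA file.

    Parameters
    ----------
    path : path to a FASTA file of windows (T is mapped to U, case ignored).
    site_type : required central base, or ``"N"`` to accept any.
    label : 0/1 applied to every record, or ``None`` to read a ``label=``
        token from each description line.
    strict : if True, any invalid record raises; if False, invalid records
        are skipped with a log message.
    """
    path = Path(path)
    samples: list[Sample] = []
    bad: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_label = label
        if rec_label is None:
            m = _LABEL_RE.search(rec.description)
            if m is None:
                raise SequenceError(
                    f"{rec.id}: no label given and no 'label=0/1' token in header"
                )
            rec_label = int(m.group(1))
        try:
            seq = normalize_sequence(str(rec.seq))
            sample = Sample(id=rec.id, seq=seq, label=rec_label, site_type=site_type)
            sample.validate(length=length)
        except SequenceError as exc:
            if strict:
                bad.append(str(exc))
                continue
            logger.warning("skipping record: %s", exc)
            continue
        samples.append(sample)
    if strict and bad:
        raise SequenceError(
            f"{len(bad)} invalid record(s) in {path.name}: " + "; ".join(bad)
        )
    return SiteDataset(samples=samples, site_type=site_type, name=path.stem)


def read_fasta_pair(
    positive_path: str | Path,
    negative_path: str | Path,
    site_type: str = "N",
    strict: bool = True,
) -> SiteDataset:
    """Read a positive/negative FASTA pair into one labelled dataset."""
    pos = read_fasta(positive_path, site_type=site_type, label=1, strict=strict)
    neg = read_fasta(negative_path, site_type=site_type, label=0, strict=strict)
    return SiteDataset(
        samples=pos.samples + neg.samples,
        site_type=site_type,
        name=f"{Path(positive_path).stem}+{Path(negative_path).stem}",
    )


def write_fasta(dataset: SiteDataset, path: str | Path) -> None:
    """Write a dataset as FASTA with ``label=`` tokens in the headers."""
    with open(path, "w") as fh:
        for s in dataset:
            fh.write(f">{s.id} label={s.label} site={s.site_type}\n{s.seq}\n")


def merge_and_deduplicate(
    datasets: Sequence[SiteDataset], name: str = "generic"
) -> SiteDataset:
    """Merge datasets into one generic (site type N) set, dropping exact
    duplicate sequences (first occurrence kept).

    Conflicting labels for an identical sequence are an error: the merged
    generic training set must be internally consistent.  Near-duplicate
    clustering (80 % identity) is delegated to an external CD-HIT run.
    """
    if not datasets:
        raise ValueError("merge_and_deduplicate requires at least one dataset")
    seen: dict[str, Sample] = {}
    merged: list[Sample] = []
    used_ids: set[str] = set()
    removed = 0
    for ds in datasets:
        for s in ds:
            prev = seen.get(s.seq)
            if prev is not None:
                if prev.label != s.label:
                    raise SequenceError(
                        f"conflicting labels for identical sequence {s.seq} "
                        f"({prev.id}: {prev.label} vs {s.id}: {s.label})"
                    )
                removed += 1
                continue
            new_id = s.id
            if new_id in used_ids:
                new_id = f"{ds.name}:{s.id}"
            used_ids.add(new_id)
            kept = Sample(id=new_id, seq=s.seq, label=s.label, site_type="N")
            seen[s.seq] = kept
            merged.append(kept)
    logger.info("merge_and_deduplicate: removed %d duplicate sequence(s)", removed)
    return SiteDataset(samples=merged, site_type="N", name=name)


def write_predictions(
    records: Iterable[PredictionRecord], path: str | Path, threshold: float = 0.5
) -> None:
    """Write prediction records as CSV (id,sequence,probability,label,model)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "sequence", "probability", "label", "model"])
        for rec in records:
            rec.validate(threshold=threshold)
            writer.writerow(
                [rec.id, rec.seq, f"{rec.probability:.6f}", rec.predicted_label, rec.model_name]
            )


def central_base_counts(dataset: SiteDataset) -> dict[str, int]:
    """Count central bases; useful when splitting a generic set by site type."""
    counts: dict[str, int] = {}
    for s in dataset:
        b = s.seq[CENTER_INDEX]
        counts[b] = counts.get(b, 0) + 1
    return counts
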