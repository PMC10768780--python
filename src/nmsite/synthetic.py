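"""Synthetic Nm-site benchmark generator.

Emulates the study design of the real benchmarks: balanced (1:1) training
sets of 41-nt windows with a fixed central nucleotide, and imbalanced
independent test sets with a 1:10 positive-to-negative ratio.  Positives
carry an implanted position-weight-matrix (PWM) motif around the central
site, mixed with background at signal strength lambda (lambda = 0 gives
label-free noise, lambda = 1 plants the motif deterministically); negatives
are i.i.d. background.  Train/test disjointness is enforced on exact
sequence identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig, compact_run_config
from .io import write_fasta
from .metrics import MetricSet
from .samples import ALPHABET, CENTER_INDEX, WINDOW_LENGTH, Sample, SiteDataset

_IDX = {c: i for i, c in enumerate(ALPHABET)}


@dataclass
class MotifSpec:
    """A PWM over offsets relative to the central site, mixed with background
    at strength ``strength`` (the lambda of the mixture)."""

    offsets: tuple[int, ...] = (-2, -1, 1, 2)
    pwm: np.ndarray | None = None  # (len(offsets), 4), rows sum to 1
    strength: float = 0.9

    def __post_init__(self) -> None:
        if self.pwm is None:
            # default: a deterministic consensus motif (G G A C across the
            # four offsets); lambda alone controls implantation fidelity
            base = np.zeros((len(self.offsets), 4))
            for row, b in zip(range(len(self.offsets)), (2, 2, 0, 1)):
                base[row, b % 4] = 1.0
            self.pwm = base
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.shape != (len(self.offsets), 4):
            raise ValueError("PWM shape must be (n_offsets, 4)")
        if not np.allclose(self.pwm.sum(axis=1), 1.0):
            raise ValueError("PWM rows must sum to 1")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")
        for off in self.offsets:
            if off == 0 or not -CENTER_INDEX <= off <= CENTER_INDEX:
                raise ValueError(f"motif offset {off} outside the 41-nt window")


@dataclass
class SynthConfig:
    site_type: str = "N"
    n_pos: int = 500
    neg_ratio: int = 10
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif: MotifSpec = field(default_factory=MotifSpec)
    seed: int = 0

    def validate(self) -> "SynthConfig":
        if self.n_pos < 1:
            raise ValueError("n_pos must be >= 1")
        if self.neg_ratio < 1:
            raise ValueError("neg_ratio must be >= 1")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or (bg < 0).any():
            raise ValueError("background must be a length-4 simplex vector")
        return self


def _draw_windows(rng: np.random.Generator, n: int, site_type: str,
                  composition) -> np.ndarray:
    codes = rng.choice(4, size=(n, WINDOW_LENGTH), p=np.asarray(composition, float))
    if site_type == "N":
        codes[:, CENTER_INDEX] = rng.integers(0, 4, size=n)
    else:
        codes[:, CENTER_INDEX] = _IDX[site_type]
    return codes


def _codes_to_samples(codes: np.ndarray, prefix: str, label: int,
                      site_type: str) -> list[Sample]:
    letters = np.array(list(ALPHABET))
    samples = []
    for i, row in enumerate(codes):
        seq = "".join(letters[row])
        st = site_type if site_type != "N" else "N"
        samples.append(Sample(id=f"{prefix}{i:06d}", seq=seq, label=label,
                              site_type=st))
    return samples


def generate_background(n: int, site_type: str = "N",
                        composition=(0.25, 0.25, 0.25, 0.25),
                        seed: int = 0, prefix: str = "neg") -> SiteDataset:
    """n i.i.d. background windows with the central base forced to
    ``site_type`` (uniform over the 4 bases when N), labelled 0."""
    rng = np.random.default_rng(seed)
    codes = _draw_windows(rng, n, site_type, composition)
    return SiteDataset(
        samples=_codes_to_samples(codes, prefix, 0, site_type),
        site_type=site_type, name=f"background-{site_type}",
    )


def generate_positives(n: int, site_type: str = "N",
                       motif: MotifSpec | None = None,
                       composition=(0.25, 0.25, 0.25, 0.25),
                       seed: int = 0, prefix: str = "pos") -> SiteDataset:
    """Background windows with each motif column resampled from the mixture
    lambda * PWM + (1 - lambda) * background; labelled 1."""
    motif = motif or MotifSpec()
    rng = np.random.default_rng(seed)
    codes = _draw_windows(rng, n, site_type, composition)
    bg = np.asarray(composition, dtype=float)
    for row, off in enumerate(motif.offsets):
        p = motif.strength * motif.pwm[row] + (1.0 - motif.strength) * bg
        codes[:, CENTER_INDEX + off] = rng.choice(4, size=n, p=p / p.sum())
    return SiteDataset(
        samples=_codes_to_samples(codes, prefix, 1, site_type),
        site_type=site_type, name=f"positives-{site_type}",
    )


def generate_benchmark(config: SynthConfig) -> tuple[SiteDataset, SiteDataset]:
    """Balanced 1:1 training set and 1:neg_ratio independent test set.

    No sequence is shared between the two sets (rejection sampling on exact
    identity); duplicates within a set are rejected as well so the exact-
    deduplication invariants hold downstream.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    seen: set[str] = set()

    def draw_unique(n: int, positive: bool, prefix: str) -> list[Sample]:
        out: list[Sample] = []
        attempts = 0
        while len(out) < n:
            attempts += 1
            if attempts > 200:
                raise ValueError(
                    "requested sizes exceed distinct-sequence capacity"
                )
            m = n - len(out)
            batch_seed = int(rng.integers(0, 2 ** 31))
            ds = (
                generate_positives(m, config.site_type, config.motif,
                                   config.background, seed=batch_seed,
                                   prefix=f"{prefix}{attempts}_")
                if positive else
                generate_background(m, config.site_type, config.background,
                                    seed=batch_seed, prefix=f"{prefix}{attempts}_")
            )
            for s in ds:
                if s.seq not in seen:
                    seen.add(s.seq)
                    out.append(s)
        return out

    train_pos = draw_unique(config.n_pos, True, "trp")
    train_neg = draw_unique(config.n_pos, False, "trn")
    test_pos = draw_unique(config.n_pos, True, "tep")
    test_neg = draw_unique(config.n_pos * config.neg_ratio, False, "ten")

    def renumber(samples: list[Sample], prefix: str) -> list[Sample]:
        return [
            Sample(id=f"{prefix}{i:06d}", seq=s.seq, label=s.label,
                   site_type=s.site_type)
            for i, s in enumerate(samples)
        ]

    train = SiteDataset(
        samples=renumber(train_pos, "train_pos_") + renumber(train_neg, "train_neg_"),
        site_type=config.site_type, name="synthetic-train",
    )
    test = SiteDataset(
        samples=renumber(test_pos, "test_pos_") + renumber(test_neg, "test_neg_"),
        site_type=config.site_type, name="synthetic-test",
    )
    train.validate()
    test.validate()
    return train, test


def write_benchmark(train: SiteDataset, test: SiteDataset, config: SynthConfig,
                    out_dir: str | Path) -> None:
    """Paired FASTA files plus a JSON manifest of the generating config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds, stem in ((train, "train"), (test, "test")):
        pos = SiteDataset([s for s in ds if s.label == 1], ds.site_type, f"{stem}-pos")
        neg = SiteDataset([s for s in ds if s.label == 0], ds.site_type, f"{stem}-neg")
        write_fasta(pos, out / f"{stem}_positives.fasta")
        write_fasta(neg, out / f"{stem}_negatives.fasta")
    manifest = {
        "site_type": config.site_type,
        "n_pos": config.n_pos,
        "neg_ratio": config.neg_ratio,
        "background": list(config.background),
        "motif_offsets": list(config.motif.offsets),
        "motif_pwm": np.asarray(config.motif.pwm).tolist(),
        "lambda": config.motif.strength,
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


@dataclass
class SanityReport:
    seed: int
    strength: float
    test_metrics: MetricSet
    passed: bool


def signal_sanity_check(
    benchmark: tuple[SiteDataset, SiteDataset],
    config: SynthConfig,
    run_config: RunConfig | None = None,
    seed: int | None = None,
) -> SanityReport:
    """Train the hybrid model on the benchmark and check discrimination.

    With an informative motif at lambda >= 0.8 the test AUC must reach 0.95;
    with lambda = 0 (no signal) it must sit in the chance band [0.45, 0.55].
    """
    from .training import evaluate, train_model  # local import to avoid cycle

    train, test = benchmark
    cfg = run_config or compact_run_config()
    s = config.seed if seed is None else seed
    predictor, _ = train_model(train, cfg, seed=s)
    ms = evaluate(predictor, test)
    lam = config.motif.strength
    if lam >= 0.8:
        passed = ms.AUC >= 0.95
    elif lam == 0.0:
        passed = 0.45 <= ms.AUC <= 0.55
    else:
        passed = True
    return SanityReport(seed=s, strength=lam, test_metrics=ms, passed=passed)
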