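"""The 14 conventional sequence descriptors.

Each encoder maps an RNA sequence over {A, C, G, U} to a fixed-length numeric
vector.  Nucleotides are ordered lexicographically A < C < G < U everywhere;
k-mers, dinucleotides and trinucleotides are enumerated in lexicographic order
under that alphabet.  All encoders are deterministic, total on valid input and
length-generic (any L >= the encoder's minimum), although the production
window length is 41.

Descriptor inventory
--------------------
BPF      one-hot nucleotide profile (4 bits per position)
NCP      nucleotide chemical properties (ring structure, hydrogen bonding,
         functional group; 3 bits per position)
DBE      dinucleotide binary encoding (16-bit one-hot per overlapping dinuc)
PS2      position-specific dinucleotide one-hot (alias of DBE under the
         default convention)
Kmer     overlapping k-mer frequencies (default k=3)
RCKmer   reverse-complement-collapsed k-mer frequencies
PseEIIP  trinucleotide frequencies weighted by summed electron-ion
         interaction pseudo-potentials
CKSNAP   composition of k-spaced nucleotide pairs (gaps 0..kmax)
ENAC     sliding-window nucleotide composition
DPCP_1   per-dinucleotide physicochemical profile (frequency x property)
DPCP_2   sequence-averaged physicochemical properties
Zcurve   144 phase-specific trinucleotide Z-curve parameters
ASLPN    adaptive skip dinucleotide composition + local position-specific
         dinucleotide frequency
MMNF     multivariate mutual information + accumulated nucleotide frequency
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

from .config import DescriptorConfig
from .samples import ALPHABET, SequenceError

DESCRIPTOR_NAMES = (
    "BPF", "NCP", "DBE", "PS2", "Kmer", "RCKmer", "PseEIIP",
    "CKSNAP", "ENAC", "DPCP_1", "DPCP_2", "Zcurve", "ASLPN", "MMNF",
)

_IDX = {c: i for i, c in enumerate(ALPHABET)}
_COMP = np.array([3, 2, 1, 0])  # A<->U, C<->G in code space

# chemical-property bits: (ring structure, hydrogen bond, functional group)
_NCP_TABLE = np.array(
    [[1, 1, 1],   # A
     [0, 1, 0],   # C
     [1, 0, 0],   # G
     [0, 0, 1]],  # U
    dtype=float,
)


@dataclass(frozen=True)
class DescriptorVector:
    """A named fixed-length descriptor output."""

    name: str
    values: np.ndarray

    @property
    def dim(self) -> int:
        return int(self.values.shape[0])

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.name}: non-finite descriptor values")


def seq_to_codes(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A=0, C=1, G=2, U=3."""
    try:
        return np.array([_IDX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise SequenceError(f"invalid character {exc.args[0]!r} in sequence") from exc


# ---------------------------------------------------------------------------
# bundled tables


def _data_path(name: str) -> Path:
    return Path(str(resources.files("nmsite").joinpath("data", name)))


@lru_cache(maxsize=None)
def load_eiip_table(path: str | None = None) -> np.ndarray:
    """Per-nucleotide electron-ion interaction pseudo-potentials (A,C,G,U)."""
    p = Path(path) if path else _data_path("eiip.tsv")
    values = np.full(4, np.nan)
    for line in p.read_text().splitlines()[1:]:
        nt, v = line.split("\t")
        values[_IDX[nt]] = float(v)
    if np.any(np.isnan(values)) or np.any(values <= 0):
        raise ValueError("EIIP table must define a positive value for all 4 bases")
    return values


@lru_cache(maxsize=None)
def load_property_table(path: str | None = None) -> tuple[tuple[str, ...], np.ndarray]:
    """Dinucleotide physicochemical property table.

    Returns (property names, 16 x n_properties matrix in lexicographic
    dinucleotide order).  The bundled default covers RNA nearest-neighbor
    stacking thermodynamics (dG37, dH, derived dS).
    """
    p = Path(path) if path else _data_path("rna_dinucleotide_properties.tsv")
    lines = p.read_text().splitlines()
    names = tuple(lines[0].split("\t")[1:])
    table = np.full((16, len(names)), np.nan)
    for line in lines[1:]:
        parts = line.split("\t")
        di = _IDX[parts[0][0]] * 4 + _IDX[parts[0][1]]
        table[di] = [float(x) for x in parts[1:]]
    if np.any(np.isnan(table)):
        raise ValueError("property table must cover all 16 dinucleotides")
    return names, table


def standardize_properties(table: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance per property across the 16 dinucleotides."""
    mean = table.mean(axis=0)
    std = table.std(axis=0)
    if np.any(std == 0):
        raise ValueError("constant physicochemical property cannot be standardized")
    return (table - mean) / std


# ---------------------------------------------------------------------------
# encoders (positional / one-hot family)


def encode_bpf(seq: str) -> np.ndarray:
    codes = seq_to_codes(seq)
    return np.eye(4)[codes].ravel()


def encode_ncp(seq: str) -> np.ndarray:
    codes = seq_to_codes(seq)
    return _NCP_TABLE[codes].ravel()


def encode_dbe(seq: str) -> np.ndarray:
    codes = seq_to_codes(seq)
    if codes.size < 2:
        raise SequenceError("DBE requires length >= 2")
    di = codes[:-1] * 4 + codes[1:]
    out = np.zeros((di.size, 16))
    out[np.arange(di.size), di] = 1.0
    return out.ravel()


def encode_ps2(seq: str) -> np.ndarray:
    """Position-specific dinucleotide one-hot; identical to DBE by default."""
    return encode_dbe(seq)


# ---------------------------------------------------------------------------
# composition family


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    if codes.size < k:
        raise SequenceError(f"sequence shorter than k={k}")
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1)
    return windows @ powers


def encode_kmer(seq: str, k: int = 3) -> np.ndarray:
    codes = seq_to_codes(seq)
    kc = _kmer_codes(codes, k)
    counts = np.bincount(kc, minlength=4 ** k).astype(float)
    return counts / kc.size


@lru_cache(maxsize=None)
def _rc_classes(k: int) -> tuple[np.ndarray, int]:
    """Map each k-mer code to its canonical reverse-complement class index."""
    n = 4 ** k
    digits = np.array(
        [[(code // 4 ** (k - 1 - j)) % 4 for j in range(k)] for j2 in [0] for code in range(n)]
    )
    powers = 4 ** np.arange(k - 1, -1, -1)
    rc_codes = (_COMP[digits[:, ::-1]] @ powers).astype(np.int64)
    canon = np.minimum(np.arange(n), rc_codes)
    uniq = np.unique(canon)
    class_of = np.searchsorted(uniq, canon)
    return class_of, uniq.size


def encode_rckmer(seq: str, k: int = 3) -> np.ndarray:
    codes = seq_to_codes(seq)
    kc = _kmer_codes(codes, k)
    class_of, n_classes = _rc_classes(k)
    counts = np.bincount(class_of[kc], minlength=n_classes).astype(float)
    return counts / kc.size


def encode_pseeiip(seq: str, eiip: np.ndarray | None = None) -> np.ndarray:
    if eiip is None:
        eiip = load_eiip_table()
    freqs = encode_kmer(seq, k=3)
    trinuc = np.array(list(itertools.product(range(4), repeat=3)))
    weights = eiip[trinuc].sum(axis=1)
    return freqs * weights


def encode_cksnap(seq: str, kmax: int = 5) -> np.ndarray:
    codes = seq_to_codes(seq)
    L = codes.size
    blocks = []
    for g in range(kmax + 1):
        n_pairs = L - g - 1
        if n_pairs < 1:
            raise SequenceError(f"CKSNAP gap {g} needs length > {g + 1}")
        pair = codes[: n_pairs] * 4 + codes[g + 1:]
        counts = np.bincount(pair, minlength=16).astype(float)
        blocks.append(counts / n_pairs)
    return np.concatenate(blocks)


def encode_enac(seq: str, window: int = 5) -> np.ndarray:
    codes = seq_to_codes(seq)
    L = codes.size
    if window > L:
        raise SequenceError(f"ENAC window {window} exceeds length {L}")
    onehot = np.eye(4)[codes]
    csum = np.vstack([np.zeros(4), np.cumsum(onehot, axis=0)])
    counts = csum[window:] - csum[:-window]
    return (counts / window).ravel()


# ---------------------------------------------------------------------------
# physicochemical family


def encode_dpcp(
    seq: str,
    table: np.ndarray | None = None,
    variant: int = 1,
    standardized: bool = True,
) -> np.ndarray:
    """Dinucleotide physicochemical profile.

    variant 1: for each property j, frequency(d) * P_j(d) over the 16
    dinucleotides (dim 16 * n_properties, property-major).
    variant 2: per-property mean over the sequence's dinucleotide positions
    (dim n_properties).
    """
    if table is None:
        _, table = load_property_table()
    if standardized:
        table = standardize_properties(table)
    codes = seq_to_codes(seq)
    if codes.size < 2:
        raise SequenceError("DPCP requires length >= 2")
    di = codes[:-1] * 4 + codes[1:]
    freqs = np.bincount(di, minlength=16).astype(float) / di.size
    if variant == 1:
        return (freqs[:, None] * table).T.ravel()
    if variant == 2:
        return freqs @ table
    raise ValueError(f"unknown DPCP variant {variant}")


# ---------------------------------------------------------------------------
# phase / information-theoretic family


def encode_zcurve(seq: str) -> np.ndarray:
    """144 phase-specific trinucleotide Z-curve parameters.

    For each reading phase (trinucleotide start index mod 3) and each
    dinucleotide prefix mn, three parameters contrast the phase-restricted
    frequencies of mnA/mnC/mnG/mnU along the purine-pyrimidine (x),
    amino-keto (y) and strong-weak hydrogen bonding (z) axes.
    """
    codes = seq_to_codes(seq)
    L = codes.size
    out = np.zeros((3, 16, 3))
    for phase in range(3):
        starts = np.arange(phase, L - 2, 3)
        if starts.size == 0:
            continue
        tri = codes[starts] * 16 + codes[starts + 1] * 4 + codes[starts + 2]
        f = np.bincount(tri, minlength=64).astype(float) / starts.size
        f = f.reshape(16, 4)  # prefix x last base (A,C,G,U)
        out[phase, :, 0] = (f[:, 0] + f[:, 2]) - (f[:, 1] + f[:, 3])  # x: AG-CU
        out[phase, :, 1] = (f[:, 0] + f[:, 1]) - (f[:, 2] + f[:, 3])  # y: AC-GU
        out[phase, :, 2] = (f[:, 0] + f[:, 3]) - (f[:, 2] + f[:, 1])  # z: AU-GC
    return out.ravel()


def encode_aslpn(seq: str, max_skip: int | None = None) -> np.ndarray:
    """Adaptive skip dinucleotide composition + local positional dinucleotide
    frequency.

    Part (a) pools ordered nucleotide pairs over all gaps 1..max_skip
    (default: L-1, i.e. every pair in the sequence) into 16 normalized
    frequencies.  Part (b) gives, for each dinucleotide position i, the
    density of that dinucleotide within the prefix of dinucleotides 1..i.
    """
    codes = seq_to_codes(seq)
    L = codes.size
    if L < 2:
        raise SequenceError("ASLPN requires length >= 2")
    G = max_skip if max_skip is not None else L - 1
    G = min(G, L - 1)
    counts = np.zeros(16)
    denom = 0
    for g in range(1, G + 1):
        pair = codes[: L - g] * 4 + codes[g:]
        counts += np.bincount(pair, minlength=16)
        denom += L - g
    skip_comp = counts / denom
    di = codes[:-1] * 4 + codes[1:]
    onehot = np.eye(16)[di]
    running = np.cumsum(onehot, axis=0)
    local = running[np.arange(di.size), di] / np.arange(1, di.size + 1)
    return np.concatenate([skip_comp, local])


_PAIRS = list(itertools.combinations_with_replacement(range(4), 2))      # 10
_TRIPLETS = list(itertools.combinations_with_replacement(range(4), 3))   # 20


def _multiset_freqs(codes: np.ndarray, order: int) -> dict[tuple[int, ...], float]:
    """Frequencies of unordered nucleotide multisets over sliding windows."""
    n = codes.size - order + 1
    freqs: dict[tuple[int, ...], float] = {}
    windows = np.lib.stride_tricks.sliding_window_view(codes, order)
    keys = np.sort(windows, axis=1)
    uniq, counts = np.unique(keys, axis=0, return_counts=True)
    for key, c in zip(uniq, counts):
        freqs[tuple(int(x) for x in key)] = float(c) / n
    return freqs


def _xlog(x: float, ratio_num: float, ratio_den: float) -> float:
    """x * ln(num/den) with the continuity conventions 0*ln -> 0 and
    zero-denominator -> 0."""
    if x == 0.0 or ratio_den == 0.0 or ratio_num == 0.0:
        return 0.0
    return float(x * np.log(ratio_num / ratio_den))


def encode_mmnf(seq: str) -> np.ndarray:
    """Multivariate mutual information over nucleotide pairs/triplets plus
    accumulated nucleotide frequency (ANF)."""
    codes = seq_to_codes(seq)
    L = codes.size
    if L < 3:
        raise SequenceError("MMNF requires length >= 3")
    f1 = np.bincount(codes, minlength=4).astype(float) / L
    f2 = _multiset_freqs(codes, 2)
    f3 = _multiset_freqs(codes, 3)

    def pair_f(a: int, b: int) -> float:
        return f2.get(tuple(sorted((a, b))), 0.0)

    def mi2(a: int, b: int) -> float:
        fab = pair_f(a, b)
        return _xlog(fab, fab, f1[a] * f1[b])

    terms = [mi2(a, b) for a, b in _PAIRS]
    for a, b, c in _TRIPLETS:
        fabc = f3.get((a, b, c), 0.0)
        cond = _xlog(fabc, fabc * f1[c], pair_f(a, c) * pair_f(b, c))
        terms.append(mi2(a, b) - cond)

    onehot = np.eye(4)[codes]
    running = np.cumsum(onehot, axis=0)
    anf = running[np.arange(L), codes] / np.arange(1, L + 1)
    return np.concatenate([np.array(terms), anf])


# ---------------------------------------------------------------------------
# registry


def descriptor_dims(config: DescriptorConfig, L: int = 41) -> dict[str, int]:
    """Expected output dimension of every descriptor for sequence length L."""
    names, _ = load_property_table(config.property_table)
    n_prop = len(names)
    _, n_rc = _rc_classes(config.rckmer_k)
    return {
        "BPF": 4 * L,
        "NCP": 3 * L,
        "DBE": 16 * (L - 1),
        "PS2": 16 * (L - 1),
        "Kmer": 4 ** config.kmer_k,
        "RCKmer": n_rc,
        "PseEIIP": 64,
        "CKSNAP": 16 * (config.cksnap_kmax + 1),
        "ENAC": 4 * (L - config.enac_window + 1),
        "DPCP_1": 16 * n_prop,
        "DPCP_2": n_prop,
        "Zcurve": 144,
        "ASLPN": 16 + (L - 1),
        "MMNF": 30 + L,
    }


def encode(seq: str, name: str, config: DescriptorConfig | None = None) -> DescriptorVector:
    """Encode one sequence with one named descriptor."""
    cfg = config or DescriptorConfig()
    _, prop = load_property_table(cfg.property_table)
    dispatch = {
        "BPF": lambda: encode_bpf(seq),
        "NCP": lambda: encode_ncp(seq),
        "DBE": lambda: encode_dbe(seq),
        "PS2": lambda: encode_ps2(seq),
        "Kmer": lambda: encode_kmer(seq, cfg.kmer_k),
        "RCKmer": lambda: encode_rckmer(seq, cfg.rckmer_k),
        "PseEIIP": lambda: encode_pseeiip(seq, load_eiip_table(cfg.eiip_table)),
        "CKSNAP": lambda: encode_cksnap(seq, cfg.cksnap_kmax),
        "ENAC": lambda: encode_enac(seq, cfg.enac_window),
        "DPCP_1": lambda: encode_dpcp(seq, prop, variant=1),
        "DPCP_2": lambda: encode_dpcp(seq, prop, variant=2),
        "Zcurve": lambda: encode_zcurve(seq),
        "ASLPN": lambda: encode_aslpn(seq, cfg.aslpn_max_skip),
        "MMNF": lambda: encode_mmnf(seq),
    }
    if name not in dispatch:
        raise ValueError(f"unknown descriptor {name!r}")
    return DescriptorVector(name=name, values=dispatch[name]())


def encode_all(seq: str, config: DescriptorConfig | None = None) -> dict[str, DescriptorVector]:
    """All 14 descriptors of one sequence, keyed by name."""
    cfg = config or DescriptorConfig()
    result = {name: encode(seq, name, cfg) for name in DESCRIPTOR_NAMES}
    dims = descriptor_dims(cfg, L=len(seq))
    for name, vec in result.items():
        if vec.dim != dims[name]:
            raise AssertionError(
                f"{name}: dim {vec.dim} does not match registry {dims[name]}"
            )
    return result


def encode_dataset(
    sequences: list[str], config: DescriptorConfig | None = None
) -> dict[str, np.ndarray]:
    """Stack the 14 descriptors over a list of sequences.

    Returns a dict name -> (n_sequences, dim) float array, the layout the
    CNN branches consume.
    """
    cfg = config or DescriptorConfig()
    if not sequences:
        raise ValueError("no sequences to encode")
    out: dict[str, list[np.ndarray]] = {name: [] for name in DESCRIPTOR_NAMES}
    for seq in sequences:
        for name, vec in encode_all(seq, cfg).items():
            out[name].append(vec.values)
    return {name: np.vstack(vals) for name, vals in out.items()}
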