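"""The pseudo k-tuple GC composition (PseKGCC) encoder and the plain
three-window k-tuple baseline.

A candidate region of length L is split into front/middle/rear windows at
eta = ceil(L*epsilon) and xi = ceil(L*delta) (1-based inclusive bounds
[1, eta], [eta+1, xi], [xi+1, L]). On the reduced {G, C, *} alphabet each
window contributes

* the normalised frequencies of its 3**k overlapping k-tuples ("k-GCC"), and
* lambda correlation tiers theta_1..theta_lambda, where theta_j is the mean
  GC skew Theta = (f_G - f_C)/(f_G + f_C) of the k-tuples sampled every j
  positions from the window start (the terminal tuple is truncated at the
  window boundary; tuples with no G or C have Theta = 0 by convention).

The two blocks are jointly normalised per window with weight w:
phi_f = f_u / (1 + w*sum(theta)), phi_theta = w*theta_j / (1 + w*sum(theta)),
giving a feature vector of dimension 3*(3**k + lambda). Windows never share
tuples: counting and tier indexing are strictly per-window.

Word order is fixed and documented: base-3 expansion with C=0, G=1, *=2,
most significant position first (so k=2 reads CC, CG, C*, GC, GG, G*, *C,
*G, **). The 4-letter baseline uses A=0, C=1, G=2, T=3 base-4 order.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import DnaRecord, ReducedSequence, reduce_alphabet

WINDOW_NAMES = ("front", "middle", "rear")

# reduced-alphabet symbol codes: C=0, G=1, *=2
_CODE = {"C": 0, "G": 1, "*": 2}
_DNA_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class DegeneratePartitionError(ValueError):
    """A window of the three-window split is empty for the given (L, epsilon, delta)."""


class ParameterSequenceError(ValueError):
    """Encoder parameters are invalid for a particular sequence length."""


class NumericDegeneracyError(ValueError):
    """The per-window normaliser 1 + w*sum(theta) is not positive."""


@dataclass(frozen=True)
class PsekgccParams:
    """The five encoder parameters.

    epsilon, delta -- window split fractions, 0 < epsilon < delta < 1
    k              -- tuple size (k >= 1)
    lam            -- highest correlation tier lambda (lam >= 0)
    w              -- weight factor in [0, 1]
    """

    epsilon: float
    delta: float
    k: int
    lam: int
    w: float

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < self.delta < 1.0:
            raise ValueError(
                f"require 0 < epsilon < delta < 1, got epsilon={self.epsilon}, "
                f"delta={self.delta}"
            )
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must be in [0, 1], got {self.w}")

    @property
    def dimension(self) -> int:
        return 3 * (3**self.k + self.lam)


@dataclass(frozen=True)
class WindowPartition:
    """Three-window split of a length-L sequence; bounds are 1-based inclusive."""

    eta: int
    xi: int
    length: int

    @property
    def bounds(self) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
        return (1, self.eta), (self.eta + 1, self.xi), (self.xi + 1, self.length)

    @property
    def window_lengths(self) -> tuple[int, int, int]:
        return self.eta, self.xi - self.eta, self.length - self.xi


@dataclass(frozen=True)
class KgccComposition:
    """Per-window normalised k-GCC frequency vectors (each of length 3**k)."""

    front: np.ndarray
    middle: np.ndarray
    rear: np.ndarray
    k: int

    @property
    def windows(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.front, self.middle, self.rear


@dataclass(frozen=True)
class ThetaTiers:
    """Per-window tier correlation factors theta_1..theta_lambda, each in [-1, 1]."""

    front: np.ndarray
    middle: np.ndarray
    rear: np.ndarray

    @property
    def windows(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.front, self.middle, self.rear


@dataclass(frozen=True)
class FeatureVector:
    """The assembled phi vector, blocked [f-block, theta-block] x (front, middle, rear)."""

    phi: np.ndarray
    params: PsekgccParams

    @property
    def dimension(self) -> int:
        return self.phi.shape[0]


def partition_windows(L: int, epsilon: float, delta: float) -> WindowPartition:
    """Split a length-L sequence at eta = ceil(L*epsilon), xi = ceil(L*delta).

    All three windows must be non-empty; otherwise a
    :class:`DegeneratePartitionError` names the offending window.

    The product is rounded to 9 decimals before the ceiling so that exact
    grid fractions are not pushed up by binary floating point (e.g.
    40 * 0.15 must give eta = 6, not 7).
    """
    if not 0.0 < epsilon < delta < 1.0:
        raise ValueError(f"require 0 < epsilon < delta < 1, got {epsilon}, {delta}")
    if L < 3:
        raise ValueError(f"sequence length must be >= 3, got {L}")
    eta = math.ceil(round(L * epsilon, 9))
    xi = math.ceil(round(L * delta, 9))
    if eta < 1:
        raise DegeneratePartitionError(f"front window empty (L={L}, eta={eta})")
    if xi <= eta:
        raise DegeneratePartitionError(
            f"middle window empty (L={L}, eta={eta}, xi={xi})"
        )
    if xi >= L:
        raise DegeneratePartitionError(f"rear window empty (L={L}, xi={xi})")
    return WindowPartition(eta=eta, xi=xi, length=L)


def enumerate_kgcc_words(k: int) -> list[str]:
    """All 3**k words over {C, G, *} in canonical base-3 order (C=0, G=1, *=2)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return ["".join(p) for p in product("CG*", repeat=k)]


def _codes(symbols: str) -> np.ndarray:
    arr = np.frombuffer(symbols.encode("ascii"), dtype=np.uint8)
    out = np.empty(arr.shape, dtype=np.int64)
    out[arr == ord("C")] = 0
    out[arr == ord("G")] = 1
    out[arr == ord("*")] = 2
    return out


def _composition_from_codes(codes: np.ndarray, k: int) -> np.ndarray:
    n = codes.shape[0] - k + 1
    if n < 1:
        raise ValueError(f"window of length {codes.shape[0]} is shorter than k={k}")
    if k == 1:
        word_ids = codes
    else:
        powers = 3 ** np.arange(k - 1, -1, -1)
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        word_ids = windows @ powers
    counts = np.bincount(word_ids, minlength=3**k).astype(float)
    return counts / n


def kgcc_composition(window: ReducedSequence | str, k: int) -> np.ndarray:
    """Normalised frequencies of the overlapping k-tuples in one window.

    Counts every start position 1..len-k+1 and divides by len-k+1; ordering
    follows :func:`enumerate_kgcc_words`. The window must be at least k long.
    """
    symbols = window.symbols if isinstance(window, ReducedSequence) else window
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return _composition_from_codes(_codes(symbols), k)


def gc_skew(tuple_symbols: str) -> float:
    """GC skew Theta = (f_G - f_C)/(f_G + f_C) of one (possibly truncated) tuple.

    Returns 0.0 for a tuple with neither G nor C (the 0/0 case), keeping the
    tier means finite; a G/C-free tuple is naturally skew-neutral.
    """
    if not tuple_symbols:
        raise ValueError("empty tuple")
    n_g = tuple_symbols.count("G")
    n_c = tuple_symbols.count("C")
    if n_g + n_c == 0:
        return 0.0
    return (n_g - n_c) / (n_g + n_c)


def _theta_from_counts(g_cum: np.ndarray, c_cum: np.ndarray, j: int, k: int) -> float:
    """Tier-j mean GC skew from prefix G/C counts of one window.

    ``g_cum``/``c_cum`` are cumulative counts with a leading 0, so the count
    inside [a, b) is cum[b] - cum[a]. Tuples start at 0-based positions
    0, j, 2j, ..., m*j with m = max(ceil((len-k)/j), 0); the terminal tuple is
    truncated at the window end, and a start past the end contributes skew 0
    (it has no G/C content) while still entering the m+1 divisor.
    """
    length = g_cum.shape[0] - 1
    m = max(math.ceil((length - k) / j), 0)
    starts = np.arange(m + 1) * j
    ends = np.minimum(starts + k, length)
    starts = np.minimum(starts, length)
    n_g = g_cum[ends] - g_cum[starts]
    n_c = c_cum[ends] - c_cum[starts]
    tot = n_g + n_c
    with np.errstate(invalid="ignore"):
        theta = np.where(tot > 0, (n_g - n_c) / np.where(tot > 0, tot, 1), 0.0)
    return float(theta.sum() / (m + 1))


def theta_tier(window: ReducedSequence | str, j: int, k: int) -> float:
    """Correlation factor theta_j of one window: mean GC skew of the k-tuples
    starting every j positions from the window start.

    With m = ceil((len-k)/j) there are m+1 tuples; the last is truncated at the
    window boundary ("all available residues"). For len <= k the window is a
    single truncated tuple. j must not exceed the window length.
    """
    symbols = window.symbols if isinstance(window, ReducedSequence) else window
    length = len(symbols)
    if j < 1:
        raise ValueError(f"tier spacing j must be >= 1, got {j}")
    if j > length:
        raise ValueError(f"tier spacing j={j} exceeds window length {length}")
    is_g = np.frombuffer(symbols.encode("ascii"), dtype=np.uint8) == ord("G")
    is_c = np.frombuffer(symbols.encode("ascii"), dtype=np.uint8) == ord("C")
    g_cum = np.concatenate(([0], np.cumsum(is_g)))
    c_cum = np.concatenate(([0], np.cumsum(is_c)))
    return _theta_from_counts(g_cum, c_cum, j, k)


def compute_theta_tiers(
    reduced: ReducedSequence | str, part: WindowPartition, k: int, lam: int
) -> ThetaTiers:
    """theta_1..theta_lambda for each of the three windows of ``reduced``."""
    symbols = reduced.symbols if isinstance(reduced, ReducedSequence) else reduced
    (f0, f1), (m0, m1), (r0, r1) = part.bounds
    segs = (symbols[f0 - 1 : f1], symbols[m0 - 1 : m1], symbols[r0 - 1 : r1])
    out = []
    for seg in segs:
        arr = np.frombuffer(seg.encode("ascii"), dtype=np.uint8)
        g_cum = np.concatenate(([0], np.cumsum(arr == ord("G"))))
        c_cum = np.concatenate(([0], np.cumsum(arr == ord("C"))))
        if lam > len(seg):
            raise ValueError(
                f"lambda={lam} exceeds window length {len(seg)}"
            )
        out.append(
            np.array(
                [_theta_from_counts(g_cum, c_cum, j, k) for j in range(1, lam + 1)]
            )
        )
    return ThetaTiers(front=out[0], middle=out[1], rear=out[2])


def compute_kgcc_composition(
    reduced: ReducedSequence | str, part: WindowPartition, k: int
) -> KgccComposition:
    """Per-window k-GCC composition of ``reduced`` under partition ``part``."""
    symbols = reduced.symbols if isinstance(reduced, ReducedSequence) else reduced
    (f0, f1), (m0, m1), (r0, r1) = part.bounds
    return KgccComposition(
        front=kgcc_composition(symbols[f0 - 1 : f1], k),
        middle=kgcc_composition(symbols[m0 - 1 : m1], k),
        rear=kgcc_composition(symbols[r0 - 1 : r1], k),
        k=k,
    )


def assemble_feature_vector(
    comp: KgccComposition, tiers: ThetaTiers, w: float
) -> np.ndarray:
    """Join compositions and tiers into the phi vector.

    Per window: phi_f = f_u / (sum f + w*sum theta) and
    phi_theta = w*theta_j / (sum f + w*sum theta); since each composition sums
    to 1 the denominator is 1 + w*sum theta. Blocks are concatenated
    front -> middle -> rear, each as [f-block, theta-block]. A non-positive
    denominator raises :class:`NumericDegeneracyError` naming the window.
    """
    blocks = []
    for name, f, th in zip(WINDOW_NAMES, comp.windows, tiers.windows):
        denom = f.sum() + w * th.sum()
        if denom <= 0:
            raise NumericDegeneracyError(
                f"{name} window: normaliser 1 + w*sum(theta) = {denom:.6g} <= 0; "
                "lower w or lambda"
            )
        blocks.append(f / denom)
        blocks.append(w * th / denom)
    return np.concatenate(blocks)


def _check_params_for_length(L: int, params: PsekgccParams) -> WindowPartition:
    part = partition_windows(L, params.epsilon, params.delta)
    wlens = part.window_lengths
    if min(wlens) < params.k:
        raise ParameterSequenceError(
            f"k={params.k} exceeds a window length (L={L}, eta={part.eta}, "
            f"xi={part.xi}, window lengths {wlens})"
        )
    if params.lam > min(wlens):
        raise ParameterSequenceError(
            f"lambda={params.lam} exceeds min window length (L={L}, "
            f"eta={part.eta}, xi={part.xi}, window lengths {wlens})"
        )
    return part


def encode_psekgcc(record: DnaRecord, params: PsekgccParams) -> FeatureVector:
    """Encode one sequence as its 3*(3**k + lambda)-dimensional PseKGCC vector.

    Pipeline: reduce to {G, C, *} -> three-window split -> per-window k-GCC
    composition and lambda skew tiers -> jointly normalised phi blocks.
    Raises :class:`ParameterSequenceError` when the windows cannot support
    (k, lambda) for this sequence length.
    """
    part = _check_params_for_length(record.length, params)
    reduced = reduce_alphabet(record)
    comp = compute_kgcc_composition(reduced, part, params.k)
    tiers = compute_theta_tiers(reduced, part, params.k, params.lam)
    phi = assemble_feature_vector(comp, tiers, params.w)
    return FeatureVector(phi=phi, params=params)


def sweep_encode(
    record: DnaRecord,
    epsilons: Sequence[float],
    deltas: Sequence[float],
    ks: Sequence[int],
    lams: Sequence[int],
    ws: Sequence[float],
):
    """Encode one record under every combination of the supplied parameter
    ranges, yielding ``(params, phi_or_None, reason)`` triples.

    Identical results to calling :func:`encode_psekgcc` per combination, but
    compositions and skew tiers are computed once per (epsilon, delta, k) and
    shared across the (lambda, w) sub-grid, which makes grid-scale sweeps
    practical. ``reason`` is "" for a successful encoding, otherwise
    "invalid" (window/k/lambda constraint) or "degenerate" (non-positive
    normaliser).
    """
    reduced = reduce_alphabet(record)
    max_lam = max(lams)
    for epsilon in epsilons:
        for delta in deltas:
            try:
                part = partition_windows(record.length, epsilon, delta)
            except ValueError:
                for k in ks:
                    for lam in lams:
                        for w in ws:
                            yield PsekgccParams(epsilon, delta, k, lam, w), None, "invalid"
                continue
            wmin = min(part.window_lengths)
            for k in ks:
                comp = None
                tiers = None
                if k <= wmin:
                    comp = compute_kgcc_composition(reduced, part, k)
                    tiers = compute_theta_tiers(
                        reduced, part, k, min(max_lam, wmin)
                    )
                if comp is not None:
                    f_sums = [f.sum() for f in comp.windows]
                for lam in lams:
                    if comp is None or lam > wmin:
                        for w in ws:
                            yield PsekgccParams(epsilon, delta, k, lam, w), None, "invalid"
                        continue
                    subs = [t[:lam] for t in
                            (tiers.front, tiers.middle, tiers.rear)]
                    th_sums = [t.sum() for t in subs]
                    for w in ws:
                        params = PsekgccParams(epsilon, delta, k, lam, w)
                        # identical arithmetic to assemble_feature_vector,
                        # with the per-window sums hoisted out of the loop
                        blocks = []
                        ok = True
                        for f, th, fs, ts in zip(comp.windows, subs, f_sums, th_sums):
                            denom = fs + w * ts
                            if denom <= 0:
                                ok = False
                                break
                            blocks.append(f / denom)
                            blocks.append(w * th / denom)
                        if ok:
                            yield params, np.concatenate(blocks), ""
                        else:
                            yield params, None, "degenerate"


def encode_3w_ktuple(
    record: DnaRecord, epsilon: float, delta: float, k: int
) -> np.ndarray:
    """Plain three-window k-tuple baseline over the 4-letter alphabet.

    Per-window normalised k-mer frequencies in A=0, C=1, G=2, T=3 base-4
    order, concatenated front -> middle -> rear; dimension 3*4**k.
    """
    part = partition_windows(record.length, epsilon, delta)
    if min(part.window_lengths) < k:
        raise ParameterSequenceError(
            f"k={k} exceeds a window length (L={record.length}, "
            f"eta={part.eta}, xi={part.xi})"
        )
    codes = np.array([_DNA_CODE[c] for c in record.sequence], dtype=np.int64)
    (f0, f1), (m0, m1), (r0, r1) = part.bounds
    powers = 4 ** np.arange(k - 1, -1, -1)
    blocks = []
    for a, b in ((f0 - 1, f1), (m0 - 1, m1), (r0 - 1, r1)):
        seg = codes[a:b]
        if k == 1:
            ids = seg
        else:
            ids = np.lib.stride_tricks.sliding_window_view(seg, k) @ powers
        counts = np.bincount(ids, minlength=4**k).astype(float)
        blocks.append(counts / (b - a - k + 1))
    return np.concatenate(blocks)


def feature_names(params: PsekgccParams) -> list[str]:
    """Canonical column names: front:CC ... front:theta1 ... rear:thetaL."""
    words = enumerate_kgcc_words(params.k)
    names = []
    for win in WINDOW_NAMES:
        names.extend(f"{win}:{wd}" for wd in words)
        names.extend(f"{win}:theta{j}" for j in range(1, params.lam + 1))
    return names


def encode_matrix(
    records: Sequence[DnaRecord], params: PsekgccParams
) -> pd.DataFrame:
    """Encode many records into a DataFrame (rows = record ids, canonical columns)."""
    phi = np.vstack([encode_psekgcc(r, params).phi for r in records])
    return pd.DataFrame(phi, index=[r.id for r in records], columns=feature_names(params))


def write_features_tsv(features: pd.DataFrame, path: str | Path) -> None:
    """Write a feature matrix as tab-separated text, first column = record id."""
    features.to_csv(path, sep="\t", index_label="id")


def read_features_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


def _cache_key(sequence: str, params: PsekgccParams) -> str:
    payload = json.dumps(
        {
            "seq": hashlib.sha256(sequence.encode()).hexdigest(),
            "epsilon": params.epsilon,
            "delta": params.delta,
            "k": params.k,
            "lam": params.lam,
            "w": params.w,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:32]


def cached_encode(
    record: DnaRecord, params: PsekgccParams, cache_dir: str | Path
) -> FeatureVector:
    """Content-addressed columnar cache: phi vectors stored as .npy keyed by a
    hash of (sequence, params). Purely an optimisation; results are identical
    to :func:`encode_psekgcc`."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = _cache_key(record.sequence, params)
    path = cache_dir / f"{key}.npy"
    if path.exists():
        return FeatureVector(phi=np.load(path), params=params)
    fv = encode_psekgcc(record, params)
    np.save(path, fv.phi)
    return fv
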