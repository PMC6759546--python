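"""Independent reference implementations used as oracles in tests.

Everything here is a deliberately naive, string-based transcription of the
method definitions (window split, k-GCC composition, GC skew, tier factors,
joint normalisation, metrics), sharing no code with the package. Kept slow
and obvious on purpose.
"""

import math


def ref_reduce(sequence: str) -> str:
    out = []
    for ch in sequence:
        if ch == "G":
            out.append("G")
        elif ch == "C":
            out.append("C")
        else:
            out.append("*")
    return "".join(out)


def ref_windows(sequence: str, epsilon: float, delta: float):
    L = len(sequence)
    # ceiling of L*fraction; products rounded to 9 decimals first (the
    # package's documented convention for exact grid fractions)
    eta = math.ceil(round(L * epsilon, 9))
    xi = math.ceil(round(L * delta, 9))
    assert 1 <= eta < xi < L, (L, eta, xi)
    return sequence[0:eta], sequence[eta:xi], sequence[xi:L]


def ref_words(k: int):
    """3**k words over C, G, * via base-3 digits (C=0, G=1, *=2), MSB first."""
    alphabet = "CG*"
    words = []
    for number in range(3**k):
        digits = []
        x = number
        for _ in range(k):
            digits.append(x % 3)
            x //= 3
        words.append("".join(alphabet[d] for d in reversed(digits)))
    return words


def ref_composition(window: str, k: int):
    n = len(window) - k + 1
    assert n >= 1
    counts = {}
    for start in range(n):
        tup = window[start : start + k]
        counts[tup] = counts.get(tup, 0) + 1
    return [counts.get(word, 0) / n for word in ref_words(k)]


def ref_gc_skew(tup: str) -> float:
    g = tup.count("G")
    c = tup.count("C")
    if g + c == 0:
        return 0.0
    return (g - c) / (g + c)


def ref_theta(window: str, j: int, k: int) -> float:
    length = len(window)
    m = math.ceil((length - k) / j)
    if m < 0:
        m = 0
    total = 0.0
    for i in range(m + 1):
        sub = window[i * j : i * j + k]  # truncated at the window end
        total += ref_gc_skew(sub) if sub else 0.0
    return total / (m + 1)


def ref_encode(sequence: str, epsilon: float, delta: float, k: int, lam: int,
               w: float):
    """Full encoder: returns the phi list, or raises AssertionError /
    ZeroDivisionError-style failure if the combination is invalid."""
    reduced = ref_reduce(sequence)
    phi = []
    for window in ref_windows(reduced, epsilon, delta):
        assert len(window) >= k and lam <= len(window)
        f = ref_composition(window, k)
        thetas = [ref_theta(window, j, k) for j in range(1, lam + 1)]
        denom = sum(f) + w * sum(thetas)
        assert denom > 0
        phi.extend(fu / denom for fu in f)
        phi.extend(w * th / denom for th in thetas)
    return phi


def ref_textbook_mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def ref_mannwhitney_auc(scores, labels) -> float:
    """AUC as the normalised U statistic with ties counted half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
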