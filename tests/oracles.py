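"""Independent brute-force oracles used to freeze expected values.

Every oracle here is deliberately written in the most direct way possible
(explicit enumeration, regex-free string stepping, automaton DP) so it
shares no code path with the implementation it checks.
"""

import numpy as np

_STOPS = ("TAA", "TAG", "TGA")


def brute_force_aug_classes(seq_dna: str) -> tuple[int, int, int]:
    """(n_uorf, n_uaug_in_frame, n_uaug_out_of_frame) by direct enumeration."""
    s = seq_dna.upper().replace("U", "T")
    n = len(s)
    n_uorf = n_in = n_out = 0
    for i in range(n):
        if s[i : i + 3] != "ATG":
            continue
        stop = False
        j = i + 3
        while j + 3 <= n:
            if s[j : j + 3] in _STOPS:
                stop = True
                break
            j += 3
        if stop:
            n_uorf += 1
        elif (n - i) % 3 == 0:
            n_in += 1
        else:
            n_out += 1
    return n_uorf, n_in, n_out


def count_hexamers_with_aug_dp() -> int:
    """Number of length-6 strings over a 4-letter alphabet containing AUG.

    Automaton DP over match progress of "AUG" (states 0, 1, 2, done).
    """
    # state transition for next letter in {A, U, G, other(C)}
    counts = {0: 1}
    done = 0
    for _ in range(6):
        new = {0: 0, 1: 0, 2: 0}
        done *= 4
        for state, c in counts.items():
            for letter in "AUGC":
                if state == 0:
                    nxt = 1 if letter == "A" else 0
                elif state == 1:
                    nxt = 2 if letter == "U" else (1 if letter == "A" else 0)
                else:  # state == 2, seen "AU"
                    if letter == "G":
                        done += c
                        continue
                    nxt = 1 if letter == "A" else 0
                new[nxt] += c
        counts = new
    return done


def naive_hexamer_counts(seq_rna: str) -> dict[str, int]:
    """Overlapping hexamer counts by direct window listing."""
    s = seq_rna.upper().replace("T", "U")
    out: dict[str, int] = {}
    for i in range(len(s) - 5):
        w = s[i : i + 6]
        out[w] = out.get(w, 0) + 1
    return out


def truncated_poisson_expected_load(lam: float, n_terms: int = 400) -> float:
    """Expected r-weighted fraction load for K ~ min(Poisson(lam), 12).

    Recomputes the fraction map and weights from their stated definitions
    (free/40S-60S: 0; 80S: 1; polysomes: 2.5, 4.5, 7.5, 12) by direct
    enumeration of the Poisson pmf.
    """
    import math

    def weight(k: int) -> float:
        k = min(k, 12)
        if k == 0:
            return 0.0  # split between two zero-weight fractions
        if k == 1:
            return 1.0
        if k <= 3:
            return 2.5
        if k <= 5:
            return 4.5
        if k <= 9:
            return 7.5
        return 12.0

    total = 0.0
    for k in range(n_terms):
        if lam > 0:
            pmf = math.exp(k * math.log(lam) - lam - math.lgamma(k + 1))
        else:
            pmf = 1.0 if k == 0 else 0.0
        total += pmf * weight(k)
    return total


def exact_mannwhitney_p_shift(a, b) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration of group labels."""
    from itertools import combinations

    pooled = list(a) + list(b)
    na = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}

    def u_stat(idx):
        ra = sum(ranks[pooled[i]] for i in idx)
        return ra - na * (na + 1) / 2

    observed = u_stat(range(na))
    n = len(pooled)
    mean_u = na * (n - na) / 2
    count = total = 0
    for idx in combinations(range(n), na):
        u = u_stat(idx)
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total
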