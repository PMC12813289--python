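"""Shared fixtures and independent oracles.

The oracle helpers here deliberately avoid the library's own code paths:
connectivity is a hand-rolled breadth-first search, the letter display is
an exhaustive minimal clique cover, trough matching is a greedy bipartite
match, and the dominant frequency comes straight from a discrete Fourier
transform.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
import pytest
from scipy.ndimage import binary_closing


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def bfs_connected(mask: np.ndarray, roi_a_mask: np.ndarray,
                  roi_b_mask: np.ndarray, close: bool = True) -> bool:
    """Breadth-first search over 8-connected foreground pixels from the
    ROI-A pixel set to the ROI-B pixel set."""
    m = np.asarray(mask, dtype=bool)
    if close:
        m = binary_closing(m, structure=np.ones((3, 3), dtype=bool))
    h, w = m.shape
    seen = np.zeros_like(m)
    q = deque()
    for r, c in np.argwhere(m & roi_a_mask):
        q.append((r, c))
        seen[r, c] = True
    target = m & roi_b_mask
    while q:
        r, c = q.popleft()
        if target[r, c]:
            return True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and m[rr, cc] and not seen[rr, cc]:
                    seen[rr, cc] = True
                    q.append((rr, cc))
    return False


def minimal_letter_count(sig: np.ndarray) -> int:
    """Exhaustive-search oracle: smallest number of letters (cliques of the
    non-significant graph) covering every NS pair and every group."""
    k = sig.shape[0]
    groups = range(k)
    ns_pairs = [(i, j) for i, j in itertools.combinations(groups, 2)
                if not sig[i, j]]
    # candidate letters = all NS-cliques (incl. singletons)
    cliques = []
    for r in range(1, k + 1):
        for sub in itertools.combinations(groups, r):
            if all(not sig[i, j] for i, j in itertools.combinations(sub, 2)):
                cliques.append(frozenset(sub))
    for n in range(1, len(cliques) + 1):
        for combo in itertools.combinations(cliques, n):
            covered_groups = set().union(*combo)
            if covered_groups != set(groups):
                continue
            if all(any({i, j} <= c for c in combo) for i, j in ns_pairs):
                return n
    raise AssertionError("unreachable: full cover always exists")


def cld_sharing(letters: dict, labels) -> np.ndarray:
    """Boolean matrix: do two groups share at least one letter?"""
    k = len(labels)
    share = np.zeros((k, k), dtype=bool)
    for i, j in itertools.combinations(range(k), 2):
        share[i, j] = share[j, i] = bool(
            set(letters[labels[i]]) & set(letters[labels[j]])
        )
    np.fill_diagonal(share, True)
    return share


def match_f1(detected: np.ndarray, truth: np.ndarray, tol: int = 2) -> float:
    """F1 of greedy one-to-one matching within ±tol frames."""
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    if detected.size == 0 and truth.size == 0:
        return 1.0
    if detected.size == 0 or truth.size == 0:
        return 0.0
    used: set[int] = set()
    tp = 0
    for d in detected:
        dists = np.abs(truth - d)
        for j in np.argsort(dists):
            if dists[j] <= tol and j not in used:
                used.add(int(j))
                tp += 1
                break
    prec = tp / detected.size
    rec = tp / truth.size
    return 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)


def fourier_rate(values: np.ndarray, fps: float) -> float:
    """Dominant-frequency pumping rate (pumps/min) from the DFT."""
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fps)
    k = 1 + int(np.argmax(power[1:]))
    return float(freqs[k] * 60.0)
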