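"""Binned contact matrices: normalization, loop-anchor pileups, loopiness.

Matrices are per-chromosome, symmetric, binned at a fixed resolution and
stored densely with an upper-triangle text representation on disk
(``bin_i<TAB>bin_j<TAB>count``). The scale targeted here (a few thousand
bins per chromosome) keeps the dense representation comfortably small.

Balancing is symmetric iterative proportional fitting to the Knight-Ruiz
fixed point: for a symmetric non-negative matrix A it finds positive
weights x with ``diag(x) A diag(x)`` having unit row sums on covered bins,
the same fixed point the KR algorithm converges to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConvergenceError, FormatError, ValidationError
from .intervals import GenomicInterval


@dataclass
class ContactMatrix:
    chrom: str
    resolution: int
    matrix: np.ndarray  # dense symmetric (n_bins x n_bins), float
    balancing_weights: np.ndarray | None = None  # per-bin, nan where masked

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("contact matrix must be square")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValidationError("contact matrix must be symmetric")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def covered_bins(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            marg = np.nansum(np.nan_to_num(self.matrix), axis=1)
        return marg > 0

    def bin_of(self, position: int) -> int:
        """Bin index of a genomic position; a position exactly on a bin
        boundary belongs to the lower bin (tie-to-lower)."""
        if position <= 0:
            return 0
        b, r = divmod(position, self.resolution)
        return int(b - 1) if r == 0 else int(b)


def read_coo(path, chrom: str, chrom_length: int, resolution: int) -> ContactMatrix:
    """Read a sparse upper-triangle COO text matrix.

    Rows are ``bin_i<TAB>bin_j<TAB>count``; an optional header line
    ``#resolution=<bp>`` is honoured (and checked against ``resolution``).
    Entries are canonicalised to i <= j and duplicates summed.
    """
    n_bins = -(-chrom_length // resolution)
    m = np.zeros((n_bins, n_bins), dtype=float)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#resolution="):
                    declared = int(line.split("=", 1)[1])
                    if declared != resolution:
                        raise FormatError(
                            f"{path}: header resolution {declared} != {resolution}"
                        )
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            i, j, c = int(f[0]), int(f[1]), float(f[2])
            if i < 0 or j < 0 or i >= n_bins or j >= n_bins:
                raise FormatError(
                    f"{path}:{lineno}: bin index out of range (n_bins={n_bins})"
                )
            if i > j:
                i, j = j, i
            m[i, j] += c
            if i != j:
                m[j, i] += c
    return ContactMatrix(chrom, resolution, m)


def write_coo(path, cm: ContactMatrix) -> None:
    with open(path, "w") as fh:
        fh.write(f"#resolution={cm.resolution}\n")
        iu = np.triu_indices(cm.n_bins)
        vals = cm.matrix[iu]
        for i, j, v in zip(iu[0], iu[1], vals):
            if v != 0 and np.isfinite(v):
                fh.write(f"{i}\t{j}\t{v:g}\n")


def coverage_normalize(cm: ContactMatrix) -> ContactMatrix:
    """Divide each entry by the product of scaled marginals.

    ``a'_ij = a_ij / (w_i w_j)`` with ``w_i = m_i / mean(m over covered
    bins)``; zero-coverage bins are masked (nan rows/columns).
    """
    m = cm.matrix
    marg = m.sum(axis=1)
    covered = marg > 0
    if not covered.any():
        raise ValidationError("cannot coverage-normalize an all-zero matrix")
    w = np.full(cm.n_bins, np.nan)
    w[covered] = marg[covered] / marg[covered].mean()
    out = m / np.outer(w, w)
    return ContactMatrix(cm.chrom, cm.resolution, out, balancing_weights=1.0 / w)


def kr_balance(
    cm: ContactMatrix, tol: float = 1e-6, max_iter: int = 3000
) -> tuple[np.ndarray, ContactMatrix]:
    """Balance to unit row sums on covered bins (symmetric IPF).

    Returns ``(weights, balanced matrix)``; ``weights[i]`` is nan for
    masked (zero-coverage) bins. Raises :class:`ConvergenceError` carrying
    the last residual when ``max_iter`` is exhausted.
    """
    m = cm.matrix
    covered = m.sum(axis=1) > 0
    if not covered.any():
        raise ValidationError("cannot balance an all-zero matrix")
    sub = m[np.ix_(covered, covered)]
    x = np.ones(sub.shape[0])
    residual = np.inf
    for _ in range(max_iter):
        rows = x * (sub @ x)
        residual = float(np.max(np.abs(rows - 1.0)))
        if residual < tol:
            break
        # disconnected covered bins inside the submatrix would give rows=0;
        # guard so they stay masked instead of dividing by zero
        safe = rows > 0
        x[safe] = x[safe] / np.sqrt(rows[safe])
        x[~safe] = 0.0
    else:
        raise ConvergenceError(
            f"KR/IPF balancing did not reach tol={tol} in {max_iter} iterations",
            residual=residual,
        )
    weights = np.full(cm.n_bins, np.nan)
    weights[covered] = x
    balanced = m * np.outer(np.nan_to_num(weights), np.nan_to_num(weights))
    balanced[~covered, :] = np.nan
    balanced[:, ~covered] = np.nan
    return weights, ContactMatrix(cm.chrom, cm.resolution, balanced, weights)


def expected_by_distance(cm: ContactMatrix) -> np.ndarray:
    """Per-diagonal mean over covered entries; nan where no coverage."""
    m = cm.matrix
    n = cm.n_bins
    exp = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(m, offset=d)
        finite = np.isfinite(diag)
        if finite.any():
            exp[d] = float(diag[finite].mean())
    return exp


@dataclass
class PileupResult:
    mean_window: np.ndarray
    n_pairs_used: int
    n_pairs_skipped: int
    loopiness: float | None = None


def loopiness(window: np.ndarray, corner_size: int = 1) -> float | None:
    """Central pixel divided by the mean of the four corner blocks.

    ``corner_size`` sets the corner block edge; missing (nan) pixels are
    excluded from the corner mean. Returns None when every corner pixel is
    missing or the corner mean is zero.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] % 2 == 0:
        raise ValidationError("pileup window must be square and odd-sized")
    k = corner_size
    if k < 1 or 2 * k > w.shape[0]:
        raise ValidationError("corner blocks must fit inside the window")
    c = w.shape[0] // 2
    center = w[c, c]
    corners = np.concatenate(
        [
            w[:k, :k].ravel(),
            w[:k, -k:].ravel(),
            w[-k:, :k].ravel(),
            w[-k:, -k:].ravel(),
        ]
    )
    corners = corners[np.isfinite(corners)]
    if corners.size == 0 or not np.isfinite(center):
        return None
    denom = float(corners.mean())
    if denom == 0:
        return None
    return float(center / denom)


def pileup(
    cm: ContactMatrix,
    pairs: Sequence[tuple[GenomicInterval, GenomicInterval]],
    halfwidth: int = 250_000,
    normalization: str = "expected",
    n_shifts: int = 10,
    seed: int | None = None,
    corner_size: int = 1,
) -> PileupResult:
    """Average normalized snippets around a list of cis locus pairs.

    Each pair is midpoint-binned (upstream locus = rows); its
    ``(2w+1) x (2w+1)`` snippet (``w = halfwidth // resolution``) is
    divided by a control — ``normalization="expected"``: the matrix's
    per-diagonal mean at each pixel's separation; ``"shifts"``: the mean of
    ``n_shifts`` snippets shifted along the diagonal by seeded random
    offsets in +-[w, 10w] bins — and the ratios are averaged pixel-wise
    ignoring missing values. Pairs closer than ``halfwidth`` to a
    chromosome edge are skipped and counted.
    """
    if normalization not in ("expected", "shifts"):
        raise ValidationError(f"unknown normalization {normalization!r}")
    w = halfwidth // cm.resolution
    size = 2 * w + 1
    n = cm.n_bins
    rng = np.random.default_rng(seed)
    exp = expected_by_distance(cm) if normalization == "expected" else None

    def snippet(bi: int, bj: int) -> np.ndarray | None:
        if bi - w < 0 or bj + w >= n or bi + w >= n or bj - w < 0:
            return None
        return cm.matrix[bi - w : bi + w + 1, bj - w : bj + w + 1].astype(float)

    used = []
    n_skipped = 0
    for a, b in pairs:
        if a.chrom != b.chrom:
            n_skipped += 1
            continue
        bi, bj = cm.bin_of(a.midpoint), cm.bin_of(b.midpoint)
        if bi > bj:
            bi, bj = bj, bi
        snip = snippet(bi, bj)
        if snip is None:
            n_skipped += 1
            continue
        if normalization == "expected":
            rows = np.arange(bi - w, bi + w + 1)
            cols = np.arange(bj - w, bj + w + 1)
            sep = np.abs(cols[None, :] - rows[:, None])
            control = exp[sep]
        else:
            controls = []
            attempts = 0
            while len(controls) < n_shifts and attempts < 50 * n_shifts:
                attempts += 1
                mag = rng.integers(max(w, 1), 10 * max(w, 1) + 1)
                sign = rng.choice((-1, 1))
                delta = int(sign * mag)
                ctrl = snippet(bi + delta, bj + delta)
                if ctrl is not None:
                    controls.append(ctrl)
            if not controls:
                n_skipped += 1
                continue
            control = np.mean(controls, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = snip / control
        ratio[~np.isfinite(ratio)] = np.nan
        used.append(ratio)
    if not used:
        raise ValidationError("pileup: zero usable pairs")
    stack = np.stack(used)
    with np.errstate(invalid="ignore"):
        mean_window = np.nanmean(stack, axis=0)
    return PileupResult(
        mean_window=mean_window,
        n_pairs_used=len(used),
        n_pairs_skipped=n_skipped,
        loopiness=loopiness(mean_window, corner_size=corner_size),
    )
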