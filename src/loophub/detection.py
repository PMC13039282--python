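"""CAD-style detection of two- and three-neuron cell assemblies.

The detector tests, for every neuron pair and every (bin size, lag)
configuration on a user grid, whether the joint spike count of the binarized
binned trains exceeds what independence predicts.  The null model conditions
on per-chunk activity margins: the recording is cut into chunks of
``chunk_bins`` bins and, within each chunk, the overlap of two fixed-size
active-bin sets is hypergeometric.  Summing the exact per-chunk means and
variances (and third cumulants) and applying a continuity-corrected
moment-matched gamma upper tail yields a fast
parametric p-value that tolerates slow non-stationarities of the firing
rates (rate changes across chunks move the margins, not the null).  A
within-chunk permutation surrogate (:func:`surrogate_null_p`) provides an
independent oracle for this approximation.

Significant pairs are extended agglomeratively: the pair's activation train
(the bins where the full pattern occurs) is treated as a new unit and tested
against every remaining neuron at the pair's bin size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .spike_io import BinnedTrain, Recording, bin_spikes

__all__ = [
    "DetectionConfig",
    "PairTestResult",
    "Assembly",
    "pairwise_coincidence_test",
    "surrogate_null_p",
    "holm_correct",
    "detect_pairs",
    "extend_to_triplets",
    "detect_assemblies",
]

#: Default temporal-resolution grid: bin sizes in seconds and the matching
#: maximum lags in bins, spanning 10 ms precision / 190 ms delay to 100 ms
#: precision / 100 ms delay.
DEFAULT_BIN_SIZES = (0.01, 0.015, 0.02, 0.025, 0.03, 0.04, 0.05, 0.06, 0.08, 0.1)
DEFAULT_MAX_LAGS = (19, 12, 9, 7, 6, 4, 3, 2, 2, 1)


@dataclass
class DetectionConfig:
    """Parameters of the assembly search.

    ``bin_sizes`` and ``max_lags`` must have equal length; entry *k* means
    "test lags -max_lags[k] .. +max_lags[k] at resolution bin_sizes[k]".
    ``chunk_bins`` is the chunk length (in bins) of the non-stationarity
    tolerant null.  ``alpha`` applies to Holm-adjusted p-values within one
    candidate's configuration family.
    """

    bin_sizes: tuple[float, ...] = DEFAULT_BIN_SIZES
    max_lags: tuple[int, ...] = DEFAULT_MAX_LAGS
    alpha: float = 0.05
    max_size: int = 3
    chunk_bins: int = 100
    reference_lags_only: bool = False

    def __post_init__(self) -> None:
        self.bin_sizes = tuple(float(b) for b in self.bin_sizes)
        self.max_lags = tuple(int(m) for m in self.max_lags)
        if len(self.bin_sizes) != len(self.max_lags):
            raise ValueError("bin_sizes and max_lags must have the same length")
        if any(b <= 0 for b in self.bin_sizes) or any(m < 0 for m in self.max_lags):
            raise ValueError("bin sizes must be positive and max lags non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.max_size not in (2, 3):
            raise ValueError("max_size must be 2 or 3")
        if self.chunk_bins < 2:
            raise ValueError("chunk_bins must be >= 2")


@dataclass
class PairTestResult:
    """Outcome of the coincidence test for one neuron pair at one bin size."""

    best_lag: int
    joint_count: int
    expected_count: float
    variance: float
    p_value: float
    bin_size: float


@dataclass
class Assembly:
    """A detected (or planted) assembly.

    ``members`` are ordered by activation (the lag-0 member first); ``lags``
    are in units of ``bin_size`` bins, non-negative and sorted, with
    ``lags[0] == 0``.  ``activation_bins`` index the bins (in the lag-0
    member's frame) where the complete pattern occurs.
    """

    members: tuple[str, ...]
    lags: tuple[int, ...]
    bin_size: float
    p_value: float
    activation_bins: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.members = tuple(self.members)
        self.lags = tuple(int(l) for l in self.lags)
        if len(self.members) != len(self.lags):
            raise ValueError("members and lags must have equal length")
        if len(set(self.members)) != len(self.members):
            raise ValueError("assembly members must be distinct")
        if self.lags and (self.lags[0] != 0 or any(np.diff(self.lags) < 0)):
            raise ValueError("lags must start at 0 and be sorted ascending")
        self.activation_bins = np.asarray(self.activation_bins, dtype=np.int64)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def lag_times(self) -> tuple[float, ...]:
        """Member activation delays in seconds relative to the first member."""
        return tuple(l * self.bin_size for l in self.lags)


# ---------------------------------------------------------------------------
# chunked-margin null


def _chunk_edges(m: int, chunk_bins: int) -> np.ndarray:
    """Non-overlapping chunk boundaries covering ``m`` bins.

    The trailing partial chunk is kept as its own (shorter) chunk; a series
    shorter than one chunk falls back to a single chunk.
    """
    if m <= 0:
        return np.array([0], dtype=np.int64)
    edges = np.arange(0, m, chunk_bins, dtype=np.int64)
    return np.append(edges, m)


def _lag_sweep(
    X: np.ndarray,
    Y: np.ndarray,
    max_lag: int,
    chunk_bins: int,
    lags: np.ndarray | None = None,
):
    """Joint-count statistics for every row pair of ``X`` x ``Y`` at every lag.

    ``X`` (p, N) and ``Y`` (q, N) are binary activity matrices on the same bin
    grid.  A positive lag ``l`` means the ``Y`` row trails the ``X`` row by
    ``l`` bins; overlap-less edge bins are dropped from both series.  Returns
    ``(lags, J, E, V, P)`` with arrays of shape ``(n_lags, p, q)``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    Y = np.ascontiguousarray(Y, dtype=np.float64)
    n = X.shape[1]
    if Y.shape[1] != n:
        raise ValueError("X and Y must share the bin grid")
    if lags is None:
        lags = np.arange(-max_lag, max_lag + 1, dtype=np.int64)
    csX = np.concatenate([np.zeros((X.shape[0], 1)), np.cumsum(X, axis=1)], axis=1)
    csY = np.concatenate([np.zeros((Y.shape[0], 1)), np.cumsum(Y, axis=1)], axis=1)

    J = np.zeros((len(lags), X.shape[0], Y.shape[0]))
    E = np.zeros_like(J)
    V = np.zeros_like(J)
    S = np.zeros_like(J)  # third cumulant of the null joint count
    for k, l in enumerate(lags):
        l = int(l)
        m = n - abs(l)
        if m <= 0:
            continue
        if l >= 0:
            xo, yo = 0, l  # X rows cover [0, m), Y rows [l, l+m)
        else:
            xo, yo = -l, 0
        J[k] = X[:, xo : xo + m] @ Y[:, yo : yo + m].T
        edges = _chunk_edges(m, chunk_bins)
        nc = np.diff(edges).astype(np.float64)
        A = csX[:, xo + edges[1:]] - csX[:, xo + edges[:-1]]
        B = csY[:, yo + edges[1:]] - csY[:, yo + edges[:-1]]
        E[k] = (A / nc) @ B.T
        w2 = np.zeros_like(nc)
        ok = nc > 1
        w2[ok] = 1.0 / (nc[ok] ** 2 * (nc[ok] - 1.0))
        V[k] = (A * (nc - A) * w2) @ (B * (nc - B)).T
        # hypergeometric third central moment is separable in the two margins
        w3 = np.zeros_like(nc)
        ok = nc > 2
        w3[ok] = 1.0 / (nc[ok] ** 3 * (nc[ok] - 1.0) * (nc[ok] - 2.0))
        S[k] = (A * (nc - A) * (nc - 2 * A) * w3) @ (B * (nc - B) * (nc - 2 * B)).T

    P = _upper_tail_p(J, E, V, S)
    return lags, J, E, V, P


def _upper_tail_p(J, E, V, S) -> np.ndarray:
    """Upper-tail p of the chunked-margin null, continuity corrected.

    The null joint count is a sum of independent per-chunk hypergeometric
    overlaps; its first three cumulants (E, V, S) are exact.  A shifted
    gamma matched to those cumulants gives the tail; when the skew is
    negligible it degrades gracefully to the normal approximation.  For
    sparse trains the per-chunk overlaps are strongly right-skewed and a
    plain normal tail would be anti-conservative.
    """
    from scipy.special import gammainc, gammaincc

    J, E, V, S = np.broadcast_arrays(J, E, V, S)
    P = np.ones(J.shape)
    x = J - E - 0.5  # continuity-corrected exceedance above the mean
    pos = V > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        skew_ok = pos & (np.abs(S) > 1e-12 * np.maximum(V, 1e-300) ** 1.5)
        normal = pos & ~skew_ok
        P[normal] = norm.sf(x[normal] / np.sqrt(V[normal]))
        # gamma fit: shape k = 4 V^3 / S^2, scale theta = S / (2 V), with the
        # distribution mirrored when the skew is negative
        k = 4.0 * V**3 / S**2
        theta = S / (2.0 * V)
        shift = 2.0 * V**2 / S  # k * theta
        right = skew_ok & (S > 0)
        z = (x[right] + shift[right]) / theta[right]
        P[right] = np.where(z > 0, gammaincc(k[right], np.maximum(z, 0.0)), 1.0)
        left = skew_ok & (S < 0)
        z = (-x[left] + np.abs(shift[left])) / np.abs(theta[left])
        P[left] = np.where(z > 0, gammainc(k[left], np.maximum(z, 0.0)), 1.0)
    return np.clip(P, 0.0, 1.0)


def _best_lag_order(J: np.ndarray, lags: np.ndarray) -> int:
    """Index of the lag maximising J; ties -> smallest |lag|, then negative."""
    key = np.lexsort((lags, np.abs(lags), -J))
    return int(key[0])


def pairwise_coincidence_test(
    a: BinnedTrain, b: BinnedTrain, max_lag: int, chunk_bins: int = 100
) -> PairTestResult:
    """Test two binned trains for excess joint activity across lags.

    Both trains are binarized; for each lag in ``[-max_lag, max_lag]`` the
    joint count J(l) (bins where both are active, after shifting ``b`` by
    ``l`` and dropping edge bins) is computed.  The lag maximising J is
    selected (ties: smaller \\|lag\\|, then the negative lag) and its upper-tail
    p-value under the chunked-margin hypergeometric null is returned, with a
    continuity-corrected moment-matched gamma tail.
    """
    if a.bin_size != b.bin_size:
        raise ValueError("trains must share a bin size")
    if a.origin != b.origin:
        raise ValueError("trains must share an origin")
    n = min(a.n_bins, b.n_bins)
    x = (a.counts[:n] > 0).astype(np.float64)[None, :]
    y = (b.counts[:n] > 0).astype(np.float64)[None, :]
    if n == 0 or x.sum() == 0 or y.sum() == 0:
        return PairTestResult(0, 0, 0.0, 0.0, 1.0, a.bin_size)
    lags, J, E, V, P = _lag_sweep(x, y, max_lag, chunk_bins)
    k = _best_lag_order(J[:, 0, 0], lags)
    return PairTestResult(
        best_lag=int(lags[k]),
        joint_count=int(round(J[k, 0, 0])),
        expected_count=float(E[k, 0, 0]),
        variance=float(V[k, 0, 0]),
        p_value=float(P[k, 0, 0]),
        bin_size=a.bin_size,
    )


def surrogate_null_p(
    a: BinnedTrain,
    b: BinnedTrain,
    lag: int,
    chunk_bins: int,
    n_surrogates: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value at one lag, shuffling active bins within chunks.

    Each surrogate independently permutes the second train's bins within
    every chunk (preserving exactly the per-chunk margins the parametric null
    conditions on); ``p = (1 + #{J_surr >= J_obs}) / (n_surrogates + 1)``.
    """
    if n_surrogates < 100:
        raise ValueError("n_surrogates must be >= 100")
    if a.bin_size != b.bin_size or a.origin != b.origin:
        raise ValueError("trains must share bin size and origin")
    n = min(a.n_bins, b.n_bins)
    lag = int(lag)
    m = n - abs(lag)
    if m <= 0:
        return 1.0
    if lag >= 0:
        x = (a.counts[:m] > 0).astype(np.float64)
        y = (b.counts[lag : lag + m] > 0).astype(np.float64)
    else:
        x = (a.counts[-lag : -lag + m] > 0).astype(np.float64)
        y = (b.counts[:m] > 0).astype(np.float64)
    j_obs = float(x @ y)

    rng = np.random.default_rng(seed)
    edges = _chunk_edges(m, chunk_bins)
    j_surr = np.zeros(n_surrogates)
    for s, e in zip(edges[:-1], edges[1:]):
        block = np.broadcast_to(y[s:e], (n_surrogates, e - s)).copy()
        rng.permuted(block, axis=1, out=block)
        j_surr += block @ x[s:e]
    return float((1 + np.sum(j_surr >= j_obs)) / (n_surrogates + 1))


def holm_correct(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (monotone, capped at 1).

    Sorted p-value *k* (0-based, ascending) is scaled by ``m - k`` and the
    running maximum enforces monotonicity.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.minimum(np.maximum.accumulate((m - np.arange(m)) * p[order]), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# pair detection across the grid


def _binarized_matrix(recording: Recording, bin_size: float) -> np.ndarray:
    trains = [
        bin_spikes(tr, bin_size, recording.t_start, recording.t_end)
        for tr in recording.neurons
    ]
    n_bins = min(t.n_bins for t in trains) if trains else 0
    return np.array([t.counts[:n_bins] > 0 for t in trains], dtype=np.float64)


def detect_pairs(recording: Recording, config: DetectionConfig | None = None) -> list[Assembly]:
    """Detect significant two-neuron assemblies at their optimal resolution.

    For each unordered neuron pair, every (bin size, lag) configuration is
    tested and the p-values Holm-corrected within that pair's configuration
    family.  Within one bin size the lag maximising the joint count is the
    candidate; across bin sizes the candidate with the smallest adjusted p is
    selected.  A pair is emitted when that adjusted p falls below ``alpha``,
    stored with the leading neuron first and a non-negative lag.
    """
    config = config or DetectionConfig()
    ids = recording.neuron_ids
    n = len(ids)
    if n < 2:
        return []

    # per bin size: full lag sweep over all neuron rows at once
    sweeps = []
    for b, max_lag in zip(config.bin_sizes, config.max_lags):
        X = _binarized_matrix(recording, b)
        if X.shape[1] == 0:
            continue
        if config.reference_lags_only:
            lag_vals = np.arange(0, max_lag + 1, dtype=np.int64)
        else:
            lag_vals = np.arange(-max_lag, max_lag + 1, dtype=np.int64)
        lags, J, E, V, P = _lag_sweep(X, X, max_lag, config.chunk_bins, lags=lag_vals)
        sweeps.append((b, lags, J, P, X))

    assemblies: list[Assembly] = []
    for i, j in itertools.combinations(range(n), 2):
        p_all: list[np.ndarray] = []
        meta: list[tuple[float, np.ndarray, np.ndarray, int]] = []
        for b, lags, J, P, _X in sweeps:
            jv = J[:, i, j]
            pv = P[:, i, j]
            p_all.append(pv)
            meta.append((b, lags, jv, len(pv)))
        if not p_all:
            continue
        adj = holm_correct(np.concatenate(p_all))
        # candidate per bin size: lag with maximal joint count
        best = None
        off = 0
        for b, lags, jv, npv in meta:
            k = _best_lag_order(jv, lags)
            cand = (float(adj[off + k]), -jv[k], b, abs(int(lags[k])), int(lags[k]))
            if best is None or cand < best:
                best = cand
                best_cfg = (b, int(lags[k]), int(round(jv[k])), float(adj[off + k]))
            off += npv
        b, lag, joint, p_adj = best_cfg
        if p_adj >= config.alpha or joint == 0:
            continue
        lead, trail = (i, j) if lag >= 0 else (j, i)
        X = next(s[4] for s in sweeps if s[0] == b)
        al = abs(lag)
        m = X.shape[1] - al
        act = (X[lead, :m] > 0) & (X[trail, al:] > 0)
        assemblies.append(
            Assembly(
                members=(ids[lead], ids[trail]),
                lags=(0, al),
                bin_size=b,
                p_value=p_adj,
                activation_bins=np.nonzero(act)[0],
            )
        )
    return assemblies


def extend_to_triplets(
    recording: Recording, pairs: list[Assembly], config: DetectionConfig | None = None
) -> list[Assembly]:
    """Agglomeratively extend significant pairs to three-neuron assemblies.

    Each pair's activation train is treated as a unit and tested against
    every other neuron at the pair's bin size; p-values are Holm-corrected
    within the assembly's candidate family (all neurons x all lags) and the
    most significant candidate below ``alpha`` is added.  Lags are re-indexed
    relative to the earliest member.  Identical member sets reached from
    different seeds collapse onto the most significant configuration.
    """
    config = config or DetectionConfig()
    if config.max_size < 3 or not pairs:
        return []
    ids = recording.neuron_ids
    index = {nid: k for k, nid in enumerate(ids)}
    bin_to_lag = dict(zip(config.bin_sizes, config.max_lags))

    mats: dict[float, np.ndarray] = {}
    found: dict[frozenset, Assembly] = {}
    for pair in pairs:
        b = pair.bin_size
        if b not in mats:
            mats[b] = _binarized_matrix(recording, b)
        X = mats[b]
        n_bins = X.shape[1]
        max_lag = bin_to_lag.get(b, max(config.max_lags))

        act = np.zeros(n_bins)
        act[pair.activation_bins[pair.activation_bins < n_bins]] = 1.0
        if act.sum() == 0:
            continue
        cand_rows = [k for k, nid in enumerate(ids) if nid not in pair.members]
        if not cand_rows:
            continue
        Z = X[cand_rows]
        lags, J, _E, _V, P = _lag_sweep(act[None, :], Z, max_lag, config.chunk_bins)
        pv = P[:, 0, :]  # (n_lags, n_candidates)
        jv = J[:, 0, :]
        adj = holm_correct(pv.ravel()).reshape(pv.shape)

        flat = [
            (float(adj[k, c]), -jv[k, c], abs(int(lags[k])), int(lags[k]), c)
            for k in range(len(lags))
            for c in range(len(cand_rows))
        ]
        p_adj, negJ, _al, lag, c = min(flat)
        if p_adj >= config.alpha or -negJ == 0:
            continue
        new_id = ids[cand_rows[c]]
        raw = [(0, pair.members[0]), (pair.lags[1], pair.members[1]), (lag, new_id)]
        raw.sort(key=lambda t: (t[0], t[1] != new_id))  # stable: pair members first on ties
        base = raw[0][0]
        members = tuple(m for _l, m in raw)
        rel_lags = tuple(l - base for l, _m in raw)

        # occurrence bins re-indexed to the earliest member's frame
        valid = (pair.activation_bins + lag >= 0) & (pair.activation_bins + lag < n_bins)
        kk = pair.activation_bins[valid]
        occ = kk[X[index[new_id], kk + lag] > 0] + min(0, lag)

        trip = Assembly(
            members=members,
            lags=rel_lags,
            bin_size=b,
            p_value=p_adj,
            activation_bins=occ,
        )
        key = frozenset(members)
        if key not in found or trip.p_value < found[key].p_value:
            found[key] = trip
    return list(found.values())


def detect_assemblies(
    recording: Recording, config: DetectionConfig | None = None
) -> tuple[list[Assembly], list[Assembly]]:
    """Run pair detection and, if configured, triplet extension."""
    config = config or DetectionConfig()
    pairs = detect_pairs(recording, config)
    triplets = extend_to_triplets(recording, pairs, config) if config.max_size >= 3 else []
    return pairs, triplets
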