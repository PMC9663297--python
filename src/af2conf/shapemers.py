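"""Shape-mers: discrete rotation-invariant structural fragment descriptors.

A protein's Cα trace is fragmented in two complementary ways — sliding
k-mers of 16 consecutive residues and radius neighborhoods of 10 Å — and
each fragment is summarized by four rotation-invariant moments of its point
cloud (second-order invariants O3, O4, O5 and the third-order norm F).
Log-binning the four invariants yields a discrete "shape-mer" id, playing
the role a k-mer plays for sequences.  Count vectors of shape-mers over a
corpus are TFIDF-weighted and factorized with non-negative matrix
factorization into p topics: W maps proteins to topics, H maps topics to
shape-mers.  Topic membership uses knee detection on the sorted topic
weights; per-residue topic scores spread each shape-mer's topic weight over
its residues with an RBF kernel on the distance to the fragment center; and
whole proteins are matched by cosine similarity of their count vectors.

With central moments μ_pqr = Σ (x−x̄)^p (y−ȳ)^q (z−z̄)^r over the fragment's
Cα points:

    O3 = μ200 + μ020 + μ002
    O4 = μ200 μ020 + μ200 μ002 + μ020 μ002 − μ110² − μ101² − μ011²
    O5 = det [[μ200, μ110, μ101], [μ110, μ020, μ011], [μ101, μ011, μ002]]
    F  = μ300² + μ030² + μ003²
         + 3 (μ210² + μ201² + μ120² + μ021² + μ102² + μ012²) + 6 μ111²

All four are invariant under rigid motion (they are the trace, second
elementary symmetric function and determinant of the covariance tensor, and
the norm of the third-order moment tensor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model import AF2Model
from .segment import Segment

__all__ = [
    "FragmentDescriptor",
    "ShapemerCounts",
    "TopicModel",
    "fragment_model",
    "moment_invariants",
    "discretize_shapemer",
    "describe_fragments",
    "shapemer_counts",
    "tfidf_matrix",
    "nmf_topics",
    "assign_topics_knee",
    "residue_topic_scores",
    "cosine_match",
]

ShapemerId = tuple[str, int, int, int, int]


@dataclass
class FragmentDescriptor:
    """A structural fragment: its member residues and (once computed) its
    moment invariants and discretized shape-mer id."""

    center: int
    kind: str  # "kmer" | "radius"
    members: np.ndarray
    invariants: tuple[float, float, float, float] | None = None
    shapemer: ShapemerId | None = None


@dataclass
class ShapemerCounts:
    """Sparse shape-mer count vector for one protein."""

    counts: dict[ShapemerId, int] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("shape-mer counts must be >= 1")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class TopicModel:
    """NMF factorization of a (protein × shape-mer) matrix: X ≈ W H."""

    W: np.ndarray
    H: np.ndarray
    vocabulary: list[ShapemerId]
    objectives: list[float]

    def __post_init__(self) -> None:
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise ValueError("W and H must be non-negative")
        if self.W.shape[1] != self.H.shape[0]:
            raise ValueError("inconsistent factor dimensions")

    @property
    def p(self) -> int:
        return self.W.shape[1]


def _units(model: AF2Model, segments: list[Segment] | None) -> list[np.ndarray]:
    """Residue-index units fragments may not cross: segments if given,
    otherwise whole chains."""
    if segments is not None:
        return [np.arange(s.start, s.end) for s in segments]
    return [model.chain_index(cid) for cid in model.chains]


def fragment_model(model: AF2Model, kind: str, k: int = 16, r: float = 10.0,
                   segments: list[Segment] | None = None) -> list[FragmentDescriptor]:
    """Enumerate fragments of one kind.

    kmer: one fragment per sliding window of k consecutive residues within a
    chain (or within each high-confidence segment when given); center is the
    window midpoint.  radius: one fragment per residue, members are all
    residues of the same unit with Cα within r Å of that residue's Cα.
    Chains shorter than k yield no k-mer fragments.
    """
    if kind not in {"kmer", "radius"}:
        raise ValueError(f"unknown fragment kind {kind!r}")
    frags: list[FragmentDescriptor] = []
    for unit in _units(model, segments):
        if kind == "kmer":
            for s in range(len(unit) - k + 1):
                members = unit[s:s + k]
                frags.append(FragmentDescriptor(int(members[k // 2]), "kmer", members))
        else:
            tree = cKDTree(model.ca[unit])
            for j, i in enumerate(unit):
                hits = tree.query_ball_point(model.ca[i], r=r)
                frags.append(FragmentDescriptor(int(i), "radius",
                                                np.sort(unit[np.asarray(hits, dtype=int)])))
    return frags


def moment_invariants(coords) -> tuple[float, float, float, float]:
    """Rotation-invariant moments (O3, O4, O5, F) of a 3-D point cloud.

    Central moments are sums over points (not means).  Degenerate clouds
    yield zeros in the affected invariants (e.g. collinear → O4 = O5 = 0).
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 1:
        raise ValueError("coords must be an (n, 3) array with n >= 1")
    c = x - x.mean(axis=0)
    xx, yy, zz = c[:, 0], c[:, 1], c[:, 2]
    m200, m020, m002 = np.sum(xx**2), np.sum(yy**2), np.sum(zz**2)
    m110, m101, m011 = np.sum(xx * yy), np.sum(xx * zz), np.sum(yy * zz)
    o3 = m200 + m020 + m002
    o4 = m200 * m020 + m200 * m002 + m020 * m002 - m110**2 - m101**2 - m011**2
    o5 = np.linalg.det(np.array([[m200, m110, m101],
                                 [m110, m020, m011],
                                 [m101, m011, m002]]))
    m300, m030, m003 = np.sum(xx**3), np.sum(yy**3), np.sum(zz**3)
    m210, m201 = np.sum(xx**2 * yy), np.sum(xx**2 * zz)
    m120, m021 = np.sum(xx * yy**2), np.sum(yy**2 * zz)
    m102, m012 = np.sum(xx * zz**2), np.sum(yy * zz**2)
    m111 = np.sum(xx * yy * zz)
    f = (m300**2 + m030**2 + m003**2
         + 3 * (m210**2 + m201**2 + m120**2 + m021**2 + m102**2 + m012**2)
         + 6 * m111**2)
    return float(o3), float(o4), float(o5), float(f)


def discretize_shapemer(descriptor: FragmentDescriptor, resolution: float) -> ShapemerId:
    """Log-bin the four invariants into a discrete shape-mer id.

    Each invariant m maps to round(resolution · sign(m) · ln(1+|m|)); the id
    is (kind, 4 integers).  The mapping is deterministic and monotone in each
    invariant.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if descriptor.invariants is None:
        raise ValueError("fragment invariants not computed")
    bins = tuple(int(round(resolution * np.sign(m) * np.log1p(abs(m))))
                 for m in descriptor.invariants)
    sid: ShapemerId = (descriptor.kind, *bins)
    descriptor.shapemer = sid
    return sid


def describe_fragments(model: AF2Model, kind: str, k: int = 16, r: float = 10.0,
                       resolution: float | None = None,
                       segments: list[Segment] | None = None,
                       normalize_by_count: bool = False) -> list[FragmentDescriptor]:
    """Fragments with invariants and shape-mer ids filled in.

    Default resolutions: 4 for k-mer fragments, 6 for radius fragments.
    ``normalize_by_count`` divides the central moments by the member count
    (size-robust variant for radius fragments).
    """
    if resolution is None:
        resolution = 4.0 if kind == "kmer" else 6.0
    frags = fragment_model(model, kind, k=k, r=r, segments=segments)
    for f in frags:
        inv = moment_invariants(model.ca[f.members])
        if normalize_by_count:
            n = len(f.members)
            # μ_pqr/n scales O3 by n⁻¹, O4 by n⁻², O5 by n⁻³, F by n⁻²·... —
            # applied on the moment level: recompute from scaled coordinates
            o3, o4, o5, fm = inv
            inv = (o3 / n, o4 / n**2, o5 / n**3, fm / n**2)
        f.invariants = inv
        discretize_shapemer(f, resolution)
    return frags


def shapemer_counts(model: AF2Model, segments: list[Segment] | None = None,
                    k: int = 16, r: float = 10.0,
                    res_kmer: float = 4.0, res_radius: float = 6.0,
                    normalize_by_count: bool = False) -> ShapemerCounts:
    """Shape-mer counts for one protein: union of the k-mer and radius
    fragment vocabularies.  When high-confidence segments are given (the
    trimmed units of an AlphaFold-style model), fragments never span segment
    boundaries and counts accumulate across all segments."""
    counts: dict[ShapemerId, int] = {}
    for kind, res in (("kmer", res_kmer), ("radius", res_radius)):
        for f in describe_fragments(model, kind, k=k, r=r, resolution=res,
                                    segments=segments,
                                    normalize_by_count=normalize_by_count):
            counts[f.shapemer] = counts.get(f.shapemer, 0) + 1
    return ShapemerCounts(counts, name=model.name)


def tfidf_matrix(counts: list[ShapemerCounts]) -> tuple[np.ndarray, list[ShapemerId]]:
    """TFIDF matrix over a corpus: proteins are documents, shape-mers terms.

    tfidf(d, t) = count(d, t) · (ln((1+n)/(1+df(t))) + 1) — raw counts as tf
    with smoothed idf, so a term present in every document keeps idf 1.
    Rows follow the input order; columns follow the sorted vocabulary.
    """
    if not counts:
        raise ValueError("empty corpus")
    vocab = sorted({t for c in counts for t in c.counts})
    if not vocab:
        raise ValueError("empty shape-mer vocabulary")
    index = {t: j for j, t in enumerate(vocab)}
    X = np.zeros((len(counts), len(vocab)))
    for i, c in enumerate(counts):
        for t, v in c.counts.items():
            X[i, index[t]] = v
    n = len(counts)
    df = np.count_nonzero(X, axis=0)
    idf = np.log((1 + n) / (1 + df)) + 1.0
    return X * idf, vocab


def _nndsvda(X: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic non-negative double-SVD initialization; zeros filled
    with the matrix mean (the 'a' variant), so multiplicative updates can
    move every entry."""
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    W = np.zeros((X.shape[0], p))
    H = np.zeros((p, X.shape[1]))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, p):
        u, v = U[:, j], Vt[j, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_un = np.linalg.norm(up), np.linalg.norm(un)
        n_vp, n_vn = np.linalg.norm(vp), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            sigma = n_up * n_vp
            if sigma > 0:
                W[:, j] = np.sqrt(S[j] * sigma) * up / n_up
                H[j, :] = np.sqrt(S[j] * sigma) * vp / n_vp
        else:
            sigma = n_un * n_vn
            if sigma > 0:
                W[:, j] = np.sqrt(S[j] * sigma) * un / n_un
                H[j, :] = np.sqrt(S[j] * sigma) * vn / n_vn
    mean = X.mean()
    W[W <= 0] = mean
    H[H <= 0] = mean
    return W, H


def nmf_topics(matrix: np.ndarray, p: int, seed: int = 0,
               max_iter: int = 500, tol: float = 1e-10) -> TopicModel:
    """Non-negative matrix factorization X ≈ W H.

    Minimizes the Frobenius objective ‖X − WH‖² by hierarchical alternating
    least squares (columnwise coordinate descent with projection to the
    non-negative orthant); initialization is the deterministic NNDSVDa
    scheme, so a fixed seed (unused by the default init) always reproduces
    the same factors.  The recorded objective sequence is non-increasing.
    """
    X = np.asarray(matrix, dtype=float)
    if np.any(X < 0):
        raise ValueError("matrix must be non-negative")
    if not 1 <= p <= min(X.shape):
        raise ValueError("p must lie in [1, min(n, m)]")
    W, H = _nndsvda(X, p)
    eps = 1e-12
    objectives = [float(np.linalg.norm(X - W @ H) ** 2)]
    for _ in range(max_iter):
        HHt = H @ H.T
        XHt = X @ H.T
        for j in range(p):
            W[:, j] = np.maximum(
                W[:, j] + (XHt[:, j] - W @ HHt[:, j]) / max(HHt[j, j], eps), 0.0)
        WtW = W.T @ W
        WtX = W.T @ X
        for j in range(p):
            H[j] = np.maximum(
                H[j] + (WtX[j] - WtW[j] @ H) / max(WtW[j, j], eps), 0.0)
        obj = float(np.linalg.norm(X - W @ H) ** 2)
        objectives.append(obj)
        if objectives[-2] - obj <= tol * max(objectives[0], eps):
            break
    return TopicModel(W=W, H=H, vocabulary=[], objectives=objectives)


def assign_topics_knee(W: np.ndarray, floor: float = 1e-9) -> list[set[int]]:
    """Assign proteins to each topic by knee detection on sorted weights.

    Per topic, weights are sorted descending and the knee is the point of
    maximum perpendicular distance to the chord from the first to the last
    point (coordinates normalized to [0, 1]); proteins with weight strictly
    above the knee weight are assigned.  Topics with (near-)uniform or
    all-zero weights — maximum chord distance below ``floor`` × max weight —
    assign nothing.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("W must be non-negative")
    n, p = W.shape
    out: list[set[int]] = []
    for t in range(p):
        col = W[:, t]
        wmax = col.max()
        if n < 3 or wmax <= 0:
            out.append(set())
            continue
        order = np.argsort(-col, kind="stable")
        w = col[order]
        span = w[0] - w[-1]
        if span <= floor * wmax:
            out.append(set())
            continue
        xs = np.arange(n) / (n - 1)
        ys = (w - w[-1]) / span
        # distance to the chord from (0, ys[0]) to (1, ys[-1]) i.e. (0,1)-(1,0)
        dist = np.abs(xs + ys - 1.0) / np.sqrt(2.0)
        knee = int(np.argmax(dist))
        if dist[knee] < floor:
            out.append(set())
            continue
        cutoff = w[knee]
        out.append({int(i) for i in order[w > cutoff]})
    return out


def residue_topic_scores(model: AF2Model, fragments: list[FragmentDescriptor],
                         H: np.ndarray, vocabulary: list[ShapemerId],
                         topic: int, sigma_rbf: float = 5.0) -> np.ndarray:
    """Per-residue contribution scores for one topic.

    Each fragment containing residue i contributes its shape-mer's topic
    weight H[t, s] times an RBF kernel of the Cα distance between residue i
    and the fragment's central residue; contributions are summed over all
    fragments.  Shape-mers absent from the vocabulary contribute 0.
    """
    if not 0 <= topic < H.shape[0]:
        raise ValueError("topic index out of range")
    index = {s: j for j, s in enumerate(vocabulary)}
    scores = np.zeros(len(model))
    two_s2 = 2.0 * sigma_rbf**2
    for f in fragments:
        if f.shapemer is None or f.shapemer not in index:
            continue
        h = H[topic, index[f.shapemer]]
        if h == 0:
            continue
        d2 = np.sum((model.ca[f.members] - model.ca[f.center])**2, axis=1)
        scores[f.members] += h * np.exp(-d2 / two_s2)
    return scores


def cosine_match(query: ShapemerCounts, corpus: list[ShapemerCounts]) -> list[tuple[int, float]]:
    """Rank corpus proteins by cosine similarity of shape-mer count vectors.

    Similarities lie in [0, 1] (non-negative vectors); ties rank the lower
    corpus index first.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    if query.total == 0:
        raise ValueError("query has no shape-mers")
    qnorm = np.sqrt(sum(v * v for v in query.counts.values()))
    sims = []
    for i, c in enumerate(corpus):
        dot = sum(v * c.counts.get(t, 0) for t, v in query.counts.items())
        cnorm = np.sqrt(sum(v * v for v in c.counts.values()))
        sims.append((i, float(dot / (qnorm * cnorm)) if cnorm > 0 else 0.0))
    return sorted(sims, key=lambda t: (-t[1], t[0]))
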