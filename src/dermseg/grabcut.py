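"""Rectangle-initialized GrabCut segmentation by iterated graph cuts.

The image is modelled as two full-covariance Gaussian mixture models
(GMMs) over RGB color — one for foreground, one for background — and a
binary label field s coupled by a contrast-sensitive smoothness prior.
The energy being minimized is

    E(s, c, θ, p) = U(s, c, θ, p) + V(s, p)

where the data term U sums, over pixels, the negative log density of
the pixel under its assigned mixture component plus the negative log
component weight, and the smoothness term V pays

    γ · exp(−β · ‖p_m − p_n‖²)

for every neighboring pixel pair with differing labels.  β is set from
the image itself as 1 / (2·⟨‖p_m − p_n‖²⟩) so the exponential
discriminates well at the image's own contrast level.

Starting from a user (or detector) supplied rectangle — outside is
definite background, inside is unknown and initially foreground — the
algorithm alternates: (a) assign each pixel to its most probable
component of its class's GMM, (b) refit the GMMs from those
assignments, (c) minimize over the labels exactly with a min-cut on the
pixel graph.  Each step can only lower E, so the energy trace is
non-increasing until the labeling is stationary.

The min cut is computed exactly on integer capacities (the continuous
energies scaled by 2²⁰ and rounded), via Dinic's algorithm from
:mod:`scipy.sparse.csgraph`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from sklearn.cluster import KMeans

from .boxes import BoundingBox

__all__ = [
    "TRIMAP_BG",
    "TRIMAP_FG",
    "TRIMAP_UNKNOWN",
    "GmmModel",
    "SmoothnessParams",
    "GrabCutConfig",
    "GrabCutError",
    "ModelDegeneracyError",
    "init_trimap",
    "fit_gmm",
    "assign_components",
    "data_term",
    "compute_beta",
    "smoothness_weight",
    "total_energy",
    "build_graph",
    "min_cut",
    "grabcut_segment",
]

logger = logging.getLogger(__name__)

TRIMAP_BG = 0  # definite background (outside the rectangle)
TRIMAP_FG = 1  # definite foreground (unused by rectangle init)
TRIMAP_UNKNOWN = 2

_COV_RIDGE = 1e-3  # εI added to covariances for invertibility
_CAP_SCALE = float(1 << 20)  # energy → integer capacity scaling
_HARD_CAP = 1e9  # terminal capacity marking a hard constraint
_DATA_CLIP = 1500.0  # reparameterized data-term ceiling; >> any smoothness cost
_LOG_2PI = float(np.log(2.0 * np.pi))


class GrabCutError(ValueError):
    pass


class ModelDegeneracyError(GrabCutError):
    """A class (foreground or background) has no pixels to model."""


@dataclass(frozen=True)
class SmoothnessParams:
    """Contrast-sensitive smoothness: coupling γ, scale β, connectivity."""

    gamma: float = 50.0
    beta: float = 0.0
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.beta < 0:
            raise GrabCutError("gamma and beta must be >= 0")
        if self.connectivity not in (4, 8):
            raise GrabCutError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class GrabCutConfig:
    """Iteration controls: C components per class, smoothness, stopping."""

    components: int = 5
    gamma: float = 50.0
    connectivity: int = 8
    max_iterations: int = 5
    tolerance: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.components < 1:
            raise GrabCutError("components must be >= 1")
        if self.max_iterations < 1:
            raise GrabCutError("max_iterations must be >= 1")


@dataclass
class GmmModel:
    """Foreground/background color mixtures θ = {π, ω, Σ}.

    Arrays are indexed ``[s, c]`` with s ∈ {0 (background), 1
    (foreground)} and c the component: ``weights`` (2, C), ``means``
    (2, C, 3), ``covariances`` (2, C, 3, 3).  Empty components carry
    zero weight.  Inverses and log-determinants are precomputed.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    inv_covariances: np.ndarray
    log_dets: np.ndarray

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @classmethod
    def from_parameters(
        cls, weights: np.ndarray, means: np.ndarray, covariances: np.ndarray
    ) -> "GmmModel":
        """Build a model from explicit {π, ω, Σ}, precomputing Σ⁻¹, log|Σ|."""
        weights = np.asarray(weights, dtype=float)
        means = np.asarray(means, dtype=float)
        covariances = np.asarray(covariances, dtype=float)
        inv = np.linalg.inv(covariances)
        _, log_dets = np.linalg.slogdet(covariances)
        return cls(weights, means, covariances, inv, log_dets)


def init_trimap(shape: tuple[int, int], rect: BoundingBox) -> np.ndarray:
    """Trimap from a rectangle: inside → unknown, outside → background.

    The rectangle is interpreted half-open and intersected with the
    image; it must leave at least one background pixel.
    """
    h, w = shape
    x1, y1 = max(0, int(np.floor(rect.x1))), max(0, int(np.floor(rect.y1)))
    x2, y2 = min(w, int(np.ceil(rect.x2))), min(h, int(np.ceil(rect.y2)))
    if x1 >= x2 or y1 >= y2:
        raise GrabCutError("rectangle does not intersect the image")
    if x1 == 0 and y1 == 0 and x2 == w and y2 == h:
        raise GrabCutError("rectangle covers the whole image: no background seed")
    trimap = np.full((h, w), TRIMAP_BG, dtype=np.uint8)
    trimap[y1:y2, x1:x2] = TRIMAP_UNKNOWN
    return trimap


def fit_gmm(
    pixels: np.ndarray,
    labels: np.ndarray,
    components: np.ndarray,
    n_components: int,
) -> GmmModel:
    """Closed-form per-group GMM fit.

    For each class s and component c: π = |group| / |class|, ω = group
    mean, Σ = group covariance + εI.  A class with no pixels at all is
    a degenerate model and raises.
    """
    pixels = np.asarray(pixels, dtype=float).reshape(-1, 3)
    labels = np.asarray(labels).reshape(-1)
    components = np.asarray(components).reshape(-1)
    if n_components < 1:
        raise GrabCutError("n_components must be >= 1")
    C = n_components
    weights = np.zeros((2, C))
    means = np.zeros((2, C, 3))
    covs = np.tile(np.eye(3) * _COV_RIDGE, (2, C, 1, 1))
    for s in (0, 1):
        cls = labels == s
        n_cls = int(cls.sum())
        if n_cls == 0:
            raise ModelDegeneracyError(f"class {s} has no pixels")
        for c in range(C):
            grp = cls & (components == c)
            n = int(grp.sum())
            if n == 0:
                continue
            weights[s, c] = n / n_cls
            pts = pixels[grp]
            means[s, c] = pts.mean(axis=0)
            if n > 1:
                d = pts - means[s, c]
                covs[s, c] = (d.T @ d) / n + np.eye(3) * _COV_RIDGE
    inv = np.linalg.inv(covs)
    _, log_dets = np.linalg.slogdet(covs)
    return GmmModel(weights, means, covs, inv, log_dets)


def _component_energies(pixels: np.ndarray, gmm: GmmModel, s: int) -> np.ndarray:
    """(N, C) matrix of data terms −log N(p; ω, Σ) − log π for class s."""
    pts = np.asarray(pixels, dtype=float).reshape(-1, 3)
    C = gmm.n_components
    out = np.full((pts.shape[0], C), np.inf)
    for c in range(C):
        if gmm.weights[s, c] <= 0:
            continue
        d = pts - gmm.means[s, c]
        maha = np.einsum("ni,ij,nj->n", d, gmm.inv_covariances[s, c], d)
        log_density = -0.5 * (3 * _LOG_2PI + gmm.log_dets[s, c] + maha)
        out[:, c] = -log_density - np.log(gmm.weights[s, c])
    return out


def assign_components(
    pixels: np.ndarray, labels: np.ndarray, gmm: GmmModel
) -> np.ndarray:
    """Most probable component of each pixel within its class's mixture.

    Equivalent to the argmin of the data term over components; ties
    break toward the lowest component index.
    """
    pts = np.asarray(pixels, dtype=float).reshape(-1, 3)
    labels = np.asarray(labels).reshape(-1)
    comps = np.zeros(pts.shape[0], dtype=np.int32)
    for s in (0, 1):
        sel = labels == s
        if sel.any():
            comps[sel] = np.argmin(_component_energies(pts[sel], gmm, s), axis=1)
    return comps


def data_term(pixel: np.ndarray, s: int, c: int, gmm: GmmModel) -> float:
    """Per-pixel likelihood energy −log N(p; ω(s,c), Σ(s,c)) − log π(s,c).

    A zero-weight component returns +inf (an impossible assignment).
    """
    if gmm.weights[s, c] <= 0:
        return float("inf")
    return float(_component_energies(np.asarray(pixel, float).reshape(1, 3), gmm, s)[0, c])


def _neighbor_offsets(connectivity: int) -> list[tuple[int, int]]:
    offs = [(0, 1), (1, 0)]
    if connectivity == 8:
        offs += [(1, 1), (1, -1)]
    return offs


def _neighbor_pairs(shape: tuple[int, int], connectivity: int):
    """Index pairs (a, b) of each undirected neighbor edge, per offset."""
    h, w = shape
    idx = np.arange(h * w).reshape(h, w)
    for dy, dx in _neighbor_offsets(connectivity):
        ya, yb = (0, dy) if dy >= 0 else (-dy, 0)
        xa, xb = (0, dx) if dx >= 0 else (-dx, 0)
        a = idx[ya : h - yb, xa : w - xb]
        b = idx[yb : h - ya, xb : w - xa]
        if a.size:
            yield a.ravel(), b.ravel()


def compute_beta(image: np.ndarray, connectivity: int = 8) -> float:
    """Contrast scale β = 1 / (2·⟨‖p_m − p_n‖²⟩) over neighbor pairs.

    A constant image has zero expected difference; β falls back to 0
    (the smoothness term then weighs every boundary equally at γ).
    """
    img = np.asarray(image, dtype=float).reshape(image.shape[0], image.shape[1], -1)
    flat = img.reshape(-1, img.shape[2])
    total, count = 0.0, 0
    for a, b in _neighbor_pairs(img.shape[:2], connectivity):
        diff = flat[a] - flat[b]
        total += float(np.sum(diff * diff))
        count += a.size
    if count == 0 or total == 0.0:
        return 0.0
    return 1.0 / (2.0 * total / count)


def smoothness_weight(p_m: np.ndarray, p_n: np.ndarray, params: SmoothnessParams) -> float:
    """Boundary penalty γ·exp(−β‖p_m − p_n‖²) for one neighbor pair."""
    d = np.asarray(p_m, float) - np.asarray(p_n, float)
    return float(params.gamma * np.exp(-params.beta * float(d @ d)))


def total_energy(
    labels: np.ndarray,
    components: np.ndarray,
    gmm: GmmModel,
    image: np.ndarray,
    params: SmoothnessParams,
) -> float:
    """E = U + V for a full labeling of an H×W image."""
    h, w = image.shape[:2]
    flat = np.asarray(image, dtype=float).reshape(-1, 3)
    lab = np.asarray(labels).reshape(-1)
    comp = np.asarray(components).reshape(-1)
    U = 0.0
    for s in (0, 1):
        sel = lab == s
        if not sel.any():
            continue
        energies = _component_energies(flat[sel], gmm, s)
        U += float(energies[np.arange(energies.shape[0]), comp[sel]].sum())
    V = 0.0
    for a, b in _neighbor_pairs((h, w), params.connectivity):
        cut = lab[a] != lab[b]
        if not cut.any():
            continue
        diff = flat[a[cut]] - flat[b[cut]]
        V += float(np.sum(params.gamma * np.exp(-params.beta * np.sum(diff * diff, axis=1))))
    return U + V


@dataclass
class PixelGraph:
    """s-t graph over pixels: terminal capacities plus neighbor edges.

    ``source_cap[i]`` is paid when pixel i ends up background (its
    background data term); ``sink_cap[i]`` when it ends up foreground.
    Definite-background pixels carry an effectively infinite sink
    capacity.  Edges are undirected with symmetric capacity.
    """

    shape: tuple[int, int]
    source_cap: np.ndarray
    sink_cap: np.ndarray
    edge_a: np.ndarray
    edge_b: np.ndarray
    edge_cap: np.ndarray


def build_graph(
    image: np.ndarray,
    trimap: np.ndarray,
    gmm: GmmModel,
    params: SmoothnessParams,
) -> PixelGraph:
    """Assemble the s-t pixel graph for one label-minimization step.

    Terminal capacities carry the data term of the *opposite* label
    (cutting the edge to the foreground terminal pays the background
    assignment cost, and vice versa), minimized over mixture components
    so the cut jointly optimizes labels and component assignment.
    Definite-background pixels get an infinite-capacity sink edge;
    neighbor edges carry the contrast-sensitive smoothness weight.
    """
    h, w = image.shape[:2]
    flat = np.asarray(image, dtype=float).reshape(-1, 3)
    tri = np.asarray(trimap).reshape(-1)

    d_bg = np.min(_component_energies(flat, gmm, 0), axis=1)
    d_fg = np.min(_component_energies(flat, gmm, 1), axis=1)
    source_cap = d_bg.copy()  # paid when the pixel is cut to background
    sink_cap = d_fg.copy()  # paid when the pixel is cut to foreground
    source_cap[tri == TRIMAP_BG] = 0.0
    sink_cap[tri == TRIMAP_BG] = _HARD_CAP
    sink_cap[tri == TRIMAP_FG] = 0.0
    source_cap[tri == TRIMAP_FG] = _HARD_CAP

    ea, eb = [], []
    for a, b in _neighbor_pairs((h, w), params.connectivity):
        ea.append(a)
        eb.append(b)
    edge_a = np.concatenate(ea)
    edge_b = np.concatenate(eb)
    diff = flat[edge_a] - flat[edge_b]
    edge_cap = params.gamma * np.exp(-params.beta * np.sum(diff * diff, axis=1))
    return PixelGraph((h, w), source_cap, sink_cap, edge_a, edge_b, edge_cap)


def min_cut(graph: PixelGraph) -> np.ndarray:
    """Exact minimum s-t cut; returns the H×W label array (1 = foreground).

    Pixels with an (effectively) infinite terminal capacity are hard
    constrained; they are contracted into their terminal, with their
    neighbor-edge weights folded into the adjacent free pixels'
    terminal capacities, so every remaining capacity is finite and
    small.  Data terms are reparameterized per pixel (subtracting the
    cheaper of the two — a constant shift of every cut) and the excess
    clipped at a level far above any smoothness cost, then scaled by
    2²⁰ to integers.  The cut is solved by max flow and the source
    side recovered by reachability in the residual graph.
    """
    h, w = graph.shape
    n = h * w
    fixed_bg = graph.sink_cap >= _HARD_CAP / 2
    fixed_fg = graph.source_cap >= _HARD_CAP / 2
    free = ~(fixed_bg | fixed_fg)
    node_of = np.full(n, -1, dtype=np.int64)
    node_of[free] = np.arange(int(free.sum()))
    m = int(free.sum())
    labels = np.zeros(n, dtype=np.uint8)
    labels[fixed_fg] = 1
    if m == 0:
        return labels.reshape(h, w)

    # reparameterize: one terminal capacity per pixel becomes zero
    base = np.minimum(graph.source_cap, graph.sink_cap)
    scap = np.where(free, graph.source_cap - base, 0.0)
    tcap = np.where(free, graph.sink_cap - base, 0.0)
    np.clip(scap, 0.0, _DATA_CLIP, out=scap)
    np.clip(tcap, 0.0, _DATA_CLIP, out=tcap)

    ea, eb, ec = graph.edge_a, graph.edge_b, graph.edge_cap
    both_free = free[ea] & free[eb]
    # edges into hard-constrained pixels become terminal capacity
    for a, b in ((ea, eb), (eb, ea)):
        sel = free[a] & fixed_bg[b]
        np.add.at(tcap, a[sel], ec[sel])
        sel = free[a] & fixed_fg[b]
        np.add.at(scap, a[sel], ec[sel])

    src, snk = m, m + 1
    fa = node_of[ea[both_free]]
    fb = node_of[eb[both_free]]
    fc = ec[both_free]

    def to_int(x: np.ndarray) -> np.ndarray:
        v = np.rint(x * _CAP_SCALE).astype(np.int64)
        return np.minimum(v, (1 << 31) - 1)  # scipy requires caps < 2**31

    rows = np.concatenate([np.full(m, src), np.arange(m), fa, fb])
    cols = np.concatenate([np.arange(m), np.full(m, snk), fb, fa])
    caps = np.concatenate([to_int(scap[free]), to_int(tcap[free]), to_int(fc), to_int(fc)])
    keep = caps > 0
    mat = csr_matrix(
        (caps[keep], (rows[keep], cols[keep])), shape=(m + 2, m + 2), dtype=np.int64
    )
    result = maximum_flow(mat, src, snk)
    # BFS from the source over positive residual capacity
    residual = mat - result.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    order = breadth_first_order(residual, src, directed=True, return_predecessors=False)
    reach = order[order < m]
    free_idx = np.flatnonzero(free)
    labels[free_idx[reach]] = 1
    return labels.reshape(h, w)


def _initial_components(
    pixels: np.ndarray, labels: np.ndarray, n_components: int, seed: int
) -> np.ndarray:
    """K-means seeding of per-class component assignments."""
    comps = np.zeros(pixels.shape[0], dtype=np.int32)
    for s in (0, 1):
        sel = np.flatnonzero(labels == s)
        if sel.size == 0:
            continue
        k = min(n_components, sel.size)
        if k == 1:
            continue
        km = KMeans(n_clusters=k, n_init=1, random_state=seed, max_iter=30)
        with warnings.catch_warnings():
            # fewer distinct colors than clusters is fine: spares go empty
            warnings.simplefilter("ignore")
            comps[sel] = km.fit_predict(pixels[sel])
    return comps


def grabcut_segment(
    image: np.ndarray,
    rect: BoundingBox,
    config: GrabCutConfig = GrabCutConfig(),
    return_trace: bool = False,
):
    """Segment the object inside ``rect`` by iterated graph cuts.

    Returns the boolean foreground mask (always a subset of the
    rectangle interior); with ``return_trace=True`` also the per-
    iteration energy values.  Iteration stops when the labels are
    stationary, the relative energy decrease falls below the tolerance,
    or ``max_iterations`` is reached.  A collapse to all-foreground or
    all-background inside the rectangle is logged and returned as-is.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    flat = image.reshape(-1, 3).astype(float)
    trimap = init_trimap((h, w), rect)
    tri = trimap.reshape(-1)
    labels = (tri != TRIMAP_BG).astype(np.uint8)  # unknown starts as foreground

    params = SmoothnessParams(
        gamma=config.gamma,
        beta=compute_beta(image, config.connectivity),
        connectivity=config.connectivity,
    )
    comps = _initial_components(flat, labels, config.components, config.seed)

    trace: list[float] = []
    prev_energy = np.inf
    for iteration in range(config.max_iterations):
        gmm = fit_gmm(flat, labels, comps, config.components)
        comps = assign_components(flat, labels, gmm)
        graph = build_graph(image, trimap, gmm, params)
        new_labels = min_cut(graph).reshape(-1)
        new_labels[tri == TRIMAP_BG] = 0  # hard constraint, by construction
        new_comps = assign_components(flat, new_labels, gmm)
        energy = total_energy(
            new_labels.reshape(h, w), new_comps, gmm, image, params
        )
        if energy > prev_energy:  # rounding guard: never accept an increase
            logger.debug("min-cut rounding produced no improvement; stopping")
            break
        changed = int(np.count_nonzero(new_labels != labels))
        labels, comps = new_labels, new_comps
        trace.append(energy)
        logger.debug(
            "grabcut iter %d: energy=%.3f changed=%d", iteration, energy, changed
        )
        if changed == 0:
            break
        if np.isfinite(prev_energy) and prev_energy > 0:
            if (prev_energy - energy) / prev_energy < config.tolerance:
                break
        prev_energy = energy

    mask = labels.reshape(h, w).astype(bool)
    unknown = trimap == TRIMAP_UNKNOWN
    n_fg = int(mask[unknown].sum())
    if n_fg == 0 or n_fg == int(unknown.sum()):
        logger.warning("grabcut collapsed to a degenerate segmentation")
    if return_trace:
        return mask, trace
    return mask
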