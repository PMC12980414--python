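"""Conformational projection and chi^2-guided ensemble selection.

Each trajectory frame is described by a vector of internal pairwise
distances (rotation/translation invariant), frames are compared by the
RMS difference of those vectors, and the dissimilarity matrix is
embedded in the plane by stress-majorizing multidimensional scaling
(SMACOF), so that planar distances approximate the conformational
dissimilarities.  The representative ensemble is then extracted with a
two-stage rule: keep the frames whose chi^2 against the experimental
curve lies in a band (default [0.9, 1.1]), estimate the 2-D point
density of those members, and return the k members nearest the density
peak within the connected high-density region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator

from .saxs import ScatteringCurve, chi_square, debye_profiles


class EnsembleError(ValueError):
    pass


# -- internal-distance features ---------------------------------------

def internal_distance_features(frames: np.ndarray, pair_sample: int = 200,
                               seed: int = 0) -> np.ndarray:
    """Map frames (n_frames, n_atoms, 3) to internal-distance vectors.

    A seeded subsample of ``pair_sample`` atom pairs is used (all pairs
    when there are fewer); the pair selection is deterministic for a
    fixed seed and identical across frames.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise EnsembleError("need >= 2 frames with consistent atom count")
    n_atoms = frames.shape[1]
    iu, ju = np.triu_indices(n_atoms, k=1)
    n_pairs = len(iu)
    if pair_sample < n_pairs:
        rng = np.random.default_rng(seed)
        pick = np.sort(rng.choice(n_pairs, size=pair_sample, replace=False))
        iu, ju = iu[pick], ju[pick]
    diff = frames[:, iu] - frames[:, ju]
    return np.sqrt(np.sum(diff * diff, axis=2))


@dataclass
class DissimilarityMatrix:
    """Condensed pairwise dissimilarities between frames."""

    n_frames: int
    condensed: np.ndarray

    def full(self) -> np.ndarray:
        return squareform(self.condensed)


def dissimilarity(features: np.ndarray) -> DissimilarityMatrix:
    """RMS difference between internal-distance vectors."""
    features = np.asarray(features, dtype=np.float64)
    cond = pdist(features) / np.sqrt(features.shape[1])
    return DissimilarityMatrix(n_frames=features.shape[0], condensed=cond)


# -- planar projection -------------------------------------------------

@dataclass
class Projection2D:
    coords: np.ndarray          # (n_frames, 2)
    stress: float               # normalized (stress-1)
    seed: int
    n_iter: int
    converged: bool
    stress_history: np.ndarray


class StressProjection(BaseEstimator):
    """Planar embedding by SMACOF stress majorization.

    Majorization guarantees a non-increasing raw stress across
    iterations; the reported ``stress_`` is the normalized Kruskal
    stress-1, sqrt(sum (d - delta)^2 / sum delta^2).  Initialization is
    seeded Gaussian, so the embedding is reproducible.

    Fitted attributes: ``embedding_``, ``stress_``, ``stress_history_``,
    ``n_iter_``, ``converged_``.
    """

    def __init__(self, seed: int = 0, max_iter: int = 300,
                 tol: float = 1e-10, n_components: int = 2):
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol
        self.n_components = n_components

    def fit(self, d: DissimilarityMatrix | np.ndarray) -> "StressProjection":
        delta = d.full() if isinstance(d, DissimilarityMatrix) else \
            np.asarray(d, dtype=np.float64)
        n = delta.shape[0]
        if n < 3:
            raise EnsembleError("need >= 3 frames to project")
        rng = np.random.default_rng(self.seed)
        scale = max(float(np.mean(delta[delta > 0])) if np.any(delta > 0)
                    else 1.0, 1e-12)
        X = rng.normal(0.0, scale, size=(n, self.n_components))
        denom = float(np.sum(delta ** 2)) or 1.0
        history = []
        prev = np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            dist = cdist(X, X)
            raw = 0.5 * float(np.sum((delta - dist) ** 2))
            history.append(raw)
            if np.isfinite(prev) and prev - raw <= self.tol * max(prev, 1.0):
                converged = True
                break
            prev = raw
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 1e-12, delta / dist, 0.0)
            B = -ratio
            np.fill_diagonal(B, 0.0)
            np.fill_diagonal(B, -B.sum(axis=1))
            X = B @ X / n
        if not converged:
            warnings.warn("SMACOF did not converge; returning best-so-far",
                          RuntimeWarning, stacklevel=2)
        dist = cdist(X, X)
        stress1 = float(np.sqrt(np.sum((delta - dist) ** 2) / denom))
        self.embedding_ = X - X.mean(axis=0)
        self.stress_ = stress1
        self.stress_history_ = np.asarray(history)
        self.n_iter_ = it
        self.converged_ = converged
        return self

    def fit_transform(self, d) -> np.ndarray:
        return self.fit(d).embedding_


def project_2d(d: DissimilarityMatrix, seed: int = 0,
               max_iter: int = 300, tol: float = 1e-10) -> Projection2D:
    est = StressProjection(seed=seed, max_iter=max_iter, tol=tol).fit(d)
    return Projection2D(coords=est.embedding_, stress=est.stress_,
                        seed=seed, n_iter=est.n_iter_,
                        converged=est.converged_,
                        stress_history=est.stress_history_)


# -- chi^2 annotation --------------------------------------------------

def annotate_chi2(frames: np.ndarray, elements: np.ndarray,
                  exp: ScatteringCurve,
                  form_factor_model: str = "constant",
                  method: str = "exact") -> np.ndarray:
    """chi^2 of every frame against the experimental curve, preserving
    frame order.  Theoretical profiles are computed on the experimental
    q grid, so no interpolation enters; ``method='binned'`` switches to
    the radial-binning Debye acceleration for large ensembles."""
    profiles = debye_profiles(frames, elements, exp.q,
                              form_factor_model=form_factor_model,
                              method=method)
    out = np.empty(len(profiles))
    for k, I_th in enumerate(profiles):
        out[k] = chi_square(exp, ScatteringCurve(exp.q, I_th)).chi2
    return out


# -- selection ---------------------------------------------------------

@dataclass
class EnsembleSelection:
    band: tuple[float, float]
    member_frames: np.ndarray     # in-band frame indices
    cluster_frames: np.ndarray    # members inside the peak density region
    density_peak: tuple[float, float]
    representatives: np.ndarray   # k member indices nearest the peak
    chi2: np.ndarray              # per frame (all frames)
    density: np.ndarray           # per member
    density_maxima: list[tuple[float, float]]
    warning: str = ""

    def to_report(self) -> dict:
        return {
            "band": list(self.band),
            "n_members": int(len(self.member_frames)),
            "n_cluster": int(len(self.cluster_frames)),
            "density_peak": [float(x) for x in self.density_peak],
            "representatives": [int(i) for i in self.representatives],
            "representative_chi2":
                [float(self.chi2[i]) for i in self.representatives],
            "density_maxima":
                [[float(a), float(b)] for a, b in self.density_maxima],
            "warning": self.warning,
        }


class EnsembleSelector(BaseEstimator):
    """Band + density-peak selection of representative conformations.

    Fitted attribute: ``selection_`` (an :class:`EnsembleSelection`).
    """

    def __init__(self, band: tuple[float, float] = (0.9, 1.1),
                 bandwidth: float | None = None, k: int = 5,
                 density_threshold: float = 0.5, grid_size: int = 80):
        self.band = band
        self.bandwidth = bandwidth
        self.k = k
        self.density_threshold = density_threshold
        self.grid_size = grid_size

    def fit(self, proj_coords: np.ndarray,
            chi2_values: np.ndarray) -> "EnsembleSelector":
        xy = np.asarray(proj_coords, dtype=np.float64)
        chi2_values = np.asarray(chi2_values, dtype=np.float64)
        if len(xy) != len(chi2_values):
            raise EnsembleError("projection and chi2 arrays are misaligned")
        lo, hi = self.band
        members = np.where((chi2_values >= lo) & (chi2_values <= hi))[0]
        if len(members) == 0:
            raise EnsembleError(
                f"no frames with chi^2 in [{lo}, {hi}]; widen the band")
        pts = xy[members]
        warning = ""

        degenerate = (
            len(members) < 3
            or np.allclose(np.ptp(pts, axis=0), 0.0)
            or np.linalg.matrix_rank(np.cov(pts.T)) < 2)
        if degenerate:
            # coincident or too few member points: trivial density
            density = np.ones(len(members))
            peak = tuple(np.mean(pts, axis=0))
            cluster = members.copy()
            maxima = [peak]
        else:
            kde = gaussian_kde(pts.T, bw_method=self.bandwidth)
            density = kde(pts.T)
            g = self.grid_size
            pad = 0.05 * np.ptp(pts, axis=0) + 1e-9
            gx = np.linspace(pts[:, 0].min() - pad[0],
                             pts[:, 0].max() + pad[0], g)
            gy = np.linspace(pts[:, 1].min() - pad[1],
                             pts[:, 1].max() + pad[1], g)
            GX, GY = np.meshgrid(gx, gy, indexing="ij")
            Z = kde(np.stack([GX.ravel(), GY.ravel()])).reshape(g, g)
            pk = np.unravel_index(np.argmax(Z), Z.shape)
            peak = (float(GX[pk]), float(GY[pk]))
            mask = Z >= self.density_threshold * Z[pk]
            labels, _ = ndimage.label(mask)
            peak_label = labels[pk]
            ix = np.clip(np.searchsorted(gx, pts[:, 0]), 0, g - 1)
            iy = np.clip(np.searchsorted(gy, pts[:, 1]), 0, g - 1)
            in_cluster = labels[ix, iy] == peak_label
            cluster = members[in_cluster]
            if len(cluster) == 0:       # grid-edge corner case
                cluster = members.copy()
            maxima = _grid_maxima(GX, GY, Z)

        if self.k > len(cluster):
            warning = (f"requested k={self.k} representatives but the "
                       f"density cluster has only {len(cluster)} members")
            warnings.warn(warning, RuntimeWarning, stacklevel=2)
        dist_to_peak = np.linalg.norm(xy[cluster] - np.asarray(peak), axis=1)
        order = np.lexsort((cluster, chi2_values[cluster], dist_to_peak))
        reps = cluster[order[:min(self.k, len(cluster))]]

        self.selection_ = EnsembleSelection(
            band=(lo, hi), member_frames=members, cluster_frames=cluster,
            density_peak=peak, representatives=reps, chi2=chi2_values,
            density=density, density_maxima=maxima, warning=warning)
        return self


def _grid_maxima(GX, GY, Z) -> list[tuple[float, float]]:
    footprint = np.ones((3, 3), dtype=bool)
    local_max = (Z == ndimage.maximum_filter(Z, footprint=footprint))
    local_max &= Z > 0.1 * Z.max()
    ii, jj = np.where(local_max)
    order = np.argsort(Z[ii, jj])[::-1]
    return [(float(GX[i, j]), float(GY[i, j]))
            for i, j in zip(ii[order], jj[order])]


def select_ensemble(proj: Projection2D, chi2_values: np.ndarray,
                    band: tuple[float, float] = (0.9, 1.1),
                    bandwidth: float | None = None,
                    k: int = 5) -> EnsembleSelection:
    sel = EnsembleSelector(band=band, bandwidth=bandwidth, k=k)
    return sel.fit(proj.coords, chi2_values).selection_


def plot_projection(proj: Projection2D, chi2_values: np.ndarray,
                    selection: EnsembleSelection | None, path) -> None:
    """Flat scatter export of the projection, coloured by chi^2, with
    in-band members and representatives highlighted (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(proj.coords[:, 0], proj.coords[:, 1], c=chi2_values,
                    s=8, cmap="coolwarm", alpha=0.7)
    fig.colorbar(sc, ax=ax, label=r"$\chi^2$")
    if selection is not None:
        m = selection.member_frames
        ax.scatter(proj.coords[m, 0], proj.coords[m, 1], s=10,
                   facecolors="none", edgecolors="orange", linewidths=0.5)
        r = selection.representatives
        ax.scatter(proj.coords[r, 0], proj.coords[r, 1], s=60, marker="*",
                   color="black", zorder=5, label="representatives")
        ax.legend(loc="best", fontsize=8)
    ax.set_xlabel("projection x")
    ax.set_ylabel("projection y")
    ax.set_title(f"stress = {proj.stress:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
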