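"""P(r) and I(q) calculators for dry atomic models.

The pair-distance distribution is a contrast-weighted histogram of all
inter-atomic distances,

    P(r_k) = sum_{i != j} (b_i - b0_i) (b_j - b0_j)  for r_ij in bin k,

on a uniform grid (default 1 A bins; a distance r falls in bin floor(r/dr),
reported at the bin center (k + 1/2) dr).  Self terms (i == j) are excluded
from P(r) and kept separately so that the Fourier mate

    I(q) = self_term + sum_k P(r_k) sin(q r_k) / (q r_k)

reproduces the Debye double sum in the small-bin limit.  No hydration layer
is modelled: the calculation is on the dry structure, with the solvent
accounted for only through the displaced-volume term b0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .model_io import ProteinModel


@dataclass
class DistanceDistribution:
    """P(r) on a uniform r grid (bin centers), with optional per-bin errors."""

    r_grid: np.ndarray
    p: np.ndarray
    errors: np.ndarray | None = None
    dmax: float = 0.0
    normalization: str = "raw"          # raw | per_molecular_weight | unit_area
    self_term: float = 0.0              # sum of w_i^2, excluded from p
    r_mean: np.ndarray | None = None    # weighted mean distance per bin

    def __post_init__(self):
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != self.p.shape:
                raise ValueError("errors not aligned with p")
            if (self.errors < 0).any():
                raise ValueError("negative errors")
        if len(self.r_grid) != len(self.p):
            raise ValueError("r_grid and p differ in length")

    @property
    def bin_width(self) -> float:
        if len(self.r_grid) < 2:
            return 1.0
        return float(self.r_grid[1] - self.r_grid[0])

    @property
    def total(self) -> float:
        return float(self.p.sum())

    def rg(self) -> float:
        """Real-space radius of gyration from the second moment of P(r).

        Uses the per-bin mean distances when the histogram carries them
        (computed P(r)); bin centers otherwise (experimental curves).
        """
        s = self.p.sum()
        if s <= 0:
            raise ValueError("P(r) has no weight")
        r = self.r_mean if self.r_mean is not None else self.r_grid
        # self pairs (r = 0) belong in the normalization: sum_ij w_i w_j r_ij^2
        # = 2 (sum w)^2 Rg^2; for experimental curves self_term is 0
        return float(np.sqrt((self.p * r**2).sum() / (2.0 * (s + self.self_term))))

    def normalized(self, mode: str = "unit_area") -> "DistanceDistribution":
        if mode == "unit_area":
            area = np.trapezoid(self.p, self.r_grid)
            fac = 1.0 / area if area > 0 else 1.0
        else:
            raise ValueError(f"unknown normalization {mode!r}")
        return DistanceDistribution(
            r_grid=self.r_grid.copy(), p=self.p * fac,
            errors=None if self.errors is None else self.errors * fac,
            dmax=self.dmax, normalization=mode, self_term=self.self_term * fac)

    def write(self, path) -> None:
        """3-column ASCII: r, P(r), sigma (0 where absent)."""
        err = self.errors if self.errors is not None else np.zeros_like(self.p)
        with open(path, "w") as fh:
            fh.write(f"# P(r)  dmax={self.dmax:.2f}  normalization={self.normalization}\n")
            for r, p, e in zip(self.r_grid, self.p, err):
                fh.write(f"{r:12.4f} {p:16.8e} {e:16.8e}\n")


@dataclass
class IntensityProfile:
    """I(q) on a strictly increasing q grid, optional sigma."""

    q_grid: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.q_grid) <= 0):
            raise ValueError("q grid not strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.intensity.shape:
                raise ValueError("sigma not aligned with intensity")

    @property
    def n_points(self) -> int:
        return len(self.q_grid)

    def write(self, path) -> None:
        """3-column ASCII in the SASBDB .dat style (q, I, sigma)."""
        sig = self.sigma if self.sigma is not None else np.zeros_like(self.intensity)
        with open(path, "w") as fh:
            fh.write(f"# {self.label}\n# q  I(q)  sigma\n")
            for q, i, s in zip(self.q_grid, self.intensity, sig):
                fh.write(f"{q:14.6e} {i:16.8e} {s:16.8e}\n")


# ---------------------------------------------------------------------------


def _pair_weights(model: ProteinModel) -> tuple[np.ndarray, np.ndarray]:
    """(distances, ordered-pair weights 2*w_i*w_j) over unordered pairs i<j."""
    w = model.contrast
    d = pdist(model.coords)
    n = model.n_atoms
    iu, ju = np.triu_indices(n, k=1)
    return d, 2.0 * w[iu] * w[ju]


def compute_pr(model: ProteinModel, bin_width: float = 1.0,
               normalization: str = "raw",
               molecular_weight: float | None = None) -> DistanceDistribution:
    """Contrast-weighted pair-distance histogram of a model.

    ``dmax`` is the largest inter-atomic distance.  With
    ``normalization='per_molecular_weight'`` the histogram is divided by the
    molecular weight in Da (pass ``molecular_weight`` or it is a no-op).
    """
    if model.n_atoms < 2:
        raise ValueError("need at least 2 atoms for P(r)")
    d, wpair = _pair_weights(model)
    dmax = float(d.max())
    nbins = int(np.floor(dmax / bin_width)) + 1
    edges = np.arange(nbins + 1) * bin_width
    p, _ = np.histogram(d, bins=edges, weights=wpair)
    centers = (edges[:-1] + edges[1:]) / 2.0
    # weighted mean distance per bin: lets the Fourier mate stay accurate
    # (and the single-distance case exact) at finite bin width
    wd, _ = np.histogram(d, bins=edges, weights=wpair * d)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_mean = np.where(p != 0, wd / p, centers)
    off = (r_mean < edges[:-1]) | (r_mean > edges[1:])  # cancelling contrasts
    r_mean = np.where(off, centers, r_mean)
    w = model.contrast
    scale = 1.0
    if normalization == "per_molecular_weight":
        if molecular_weight is None or molecular_weight <= 0:
            raise ValueError("per_molecular_weight requires molecular_weight > 0")
        scale = 1.0 / molecular_weight
    return DistanceDistribution(
        r_grid=centers, p=p * scale, dmax=dmax,
        normalization=normalization, self_term=float((w**2).sum()) * scale,
        r_mean=r_mean)


def rg_from_model(model: ProteinModel) -> float:
    """Contrast-weighted radius of gyration from coordinates."""
    w = model.contrast
    s = w.sum()
    if s == 0:
        raise ValueError("all-zero contrast")
    center = (w[:, None] * model.coords).sum(axis=0) / s
    d2 = ((model.coords - center) ** 2).sum(axis=1)
    rg2 = (w * d2).sum() / s
    return float(np.sqrt(rg2))


def debye_iq(model: ProteinModel, q_grid, chunk: int = 64) -> IntensityProfile:
    """Exact Debye-sum intensity of a dry model on a q grid.

    I(q) = sum_i w_i^2 + sum_{i != j} w_i w_j sin(q r_ij)/(q r_ij).
    """
    q = np.asarray(q_grid, dtype=float)
    w = model.contrast
    self_term = float((w**2).sum())
    if model.n_atoms < 2:
        return IntensityProfile(q_grid=q, intensity=np.full_like(q, self_term),
                                label=model.label)
    d, wpair = _pair_weights(model)
    out = np.empty_like(q)
    for lo in range(0, len(q), chunk):
        qc = q[lo:lo + chunk, None]
        out[lo:lo + chunk] = (wpair * np.sinc(qc * d / np.pi)).sum(axis=1)
    return IntensityProfile(q_grid=q, intensity=self_term + out, label=model.label)


def pr_to_iq(pr: DistanceDistribution, q_grid, self_term: float | None = None) -> IntensityProfile:
    """Fourier mate of a binned P(r): I(q) = self + sum_k p_k sinc(q r_k)."""
    q = np.asarray(q_grid, dtype=float)
    st = pr.self_term if self_term is None else self_term
    r_eval = pr.r_mean if pr.r_mean is not None else pr.r_grid
    arg = q[:, None] * r_eval[None, :] / np.pi
    intensity = st + (pr.p[None, :] * np.sinc(arg)).sum(axis=1)
    return IntensityProfile(q_grid=q, intensity=intensity)


def interpolate_profile(profile: IntensityProfile, target_q_grid) -> IntensityProfile:
    """Linear interpolation of I (and sigma) onto a new q grid; no extrapolation."""
    tq = np.asarray(target_q_grid, dtype=float)
    if tq.min() < profile.q_grid[0] - 1e-12 or tq.max() > profile.q_grid[-1] + 1e-12:
        raise ValueError(
            f"target grid [{tq.min():g}, {tq.max():g}] outside source "
            f"[{profile.q_grid[0]:g}, {profile.q_grid[-1]:g}]")
    intensity = np.interp(tq, profile.q_grid, profile.intensity)
    sigma = None
    if profile.sigma is not None:
        sigma = np.interp(tq, profile.q_grid, profile.sigma)
    return IntensityProfile(q_grid=tq, intensity=intensity, sigma=sigma,
                            label=profile.label)
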