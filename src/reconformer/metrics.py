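"""Image-quality assessment suite: SSIM, NMI, JSD, sharpness, SNR, CNR.

SSIM needs a voxel-matched reference; NMI and JSD compare intensity
distributions and tolerate differing grids; the average-edge-strength (AES)
sharpness, SNR and CNR need no reference at all. SNR and CNR rely on a
GM/WM/CSF segmentation, for which a simple Otsu + k-means stand-in
segmenter is provided (its purpose is the SNR/CNR statistics, not
morphometry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import jensenshannon
from skimage.feature import canny
from skimage.filters import threshold_otsu
from skimage.metrics import structural_similarity
from sklearn.cluster import KMeans

from .volume import Volume, VolumeError, resample_to_lattice


class MetricError(ValueError):
    pass


class NoEdgesError(MetricError):
    """Canny found no edges; AES is undefined rather than silently zero."""


# ---------------------------------------------------------------------------
# histograms / information metrics
# ---------------------------------------------------------------------------


def _as_array(v) -> np.ndarray:
    return v.data if isinstance(v, Volume) else np.asarray(v, dtype=np.float64)


def intensity_histogram(x, bins: int, range_: tuple[float, float]) -> np.ndarray:
    """Normalized intensity histogram (masses sum to 1)."""
    h, _ = np.histogram(_as_array(x).ravel(), bins=bins, range=range_)
    total = h.sum()
    if total == 0:
        raise MetricError("empty histogram")
    return h / total


def _joint_hist(a: np.ndarray, b: np.ndarray, bins: int) -> np.ndarray:
    h, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    return h / h.sum()


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(a, b, bins: int = 32) -> float:
    """MI in bits from a dense bins x bins joint intensity histogram."""
    x, y = _as_array(a), _as_array(b)
    if x.shape != y.shape:
        raise MetricError("inputs must share a lattice; resample first")
    if x.max() == x.min() or y.max() == y.min():
        raise MetricError("constant image has zero marginal entropy")
    pxy = _joint_hist(x, y, bins)
    px, py = pxy.sum(axis=1), pxy.sum(axis=0)
    return _entropy_bits(px) + _entropy_bits(py) - _entropy_bits(pxy.ravel())


def nmi(x, ref, bins: int = 256) -> float:
    """Normalized mutual information (H(x)+H(ref))/H(x,ref); 2 iff identical."""
    a, b = _as_array(x), _as_array(ref)
    if a.max() == a.min() or b.max() == b.min():
        raise MetricError("constant image")
    if a.shape != b.shape:
        # distribution-level pairing is undefined on unequal grids; pair
        # after flattening requires equal counts, so fall back to resampling
        raise MetricError("nmi requires paired voxels; resample first")
    pxy = _joint_hist(a, b, bins)
    hx = _entropy_bits(pxy.sum(axis=1))
    hy = _entropy_bits(pxy.sum(axis=0))
    hxy = _entropy_bits(pxy.ravel())
    return (hx + hy) / hxy


def jsd_hist(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in bits between two histograms, in [0, 1]."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.sum() == 0 or q.sum() == 0:
        raise MetricError("empty histogram")
    d = jensenshannon(p, q, base=2.0)
    return float(d * d)


def jsd(x, ref, bins: int = 256) -> float:
    """JSD between the two marginal intensity histograms over a shared range."""
    a, b = _as_array(x), _as_array(ref)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        hi = lo + 1.0
    p = intensity_histogram(a, bins, (lo, hi))
    q = intensity_histogram(b, bins, (lo, hi))
    return jsd_hist(p, q)


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------


def ssim(x, ref) -> float:
    """Mean local SSIM (Gaussian window sigma=1.5, K1=0.01, K2=0.03).

    If lattices differ, the evaluated image is resampled to the reference
    lattice first. Dynamic range is taken from the reference.
    """
    if isinstance(x, Volume) and isinstance(ref, Volume) and x.shape != ref.shape:
        x = resample_to_lattice(x, ref.spacing, ref.shape, "trilinear")
    a, b = _as_array(x), _as_array(ref)
    if a.shape != b.shape:
        raise MetricError("shape mismatch")
    drange = float(b.max() - b.min())
    if drange == 0:
        raise MetricError("constant reference has no dynamic range")
    return float(
        structural_similarity(
            a,
            b,
            data_range=drange,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


# ---------------------------------------------------------------------------
# sharpness (AES)
# ---------------------------------------------------------------------------


def aes(
    vol,
    axis: int = 2,
    exponent: str = "squared",
    canny_low_fraction: float = 0.4,
) -> float:
    """Average edge strength, slice-wise in 2-D along ``axis``.

    Per slice, a Canny mask E selects edge pixels and Prewitt kernels give
    the gradient G; the statistic is sum_k E_k * ||G_k||^2 / sum_k E_k
    accumulated over all slices (``exponent='magnitude'`` uses ||G_k||
    instead). Canny's high threshold is the Otsu threshold of the gradient
    magnitudes, the low threshold ``canny_low_fraction`` times that.
    """
    arr = _as_array(vol)
    if arr.max() == arr.min():
        raise NoEdgesError("constant image has no edges")
    arr = np.moveaxis(arr, axis, 0)
    num = 0.0
    den = 0.0
    for sl in arr:
        gx = ndimage.prewitt(sl, axis=0, mode="reflect")
        gy = ndimage.prewitt(sl, axis=1, mode="reflect")
        g2 = gx * gx + gy * gy
        gmag = np.sqrt(g2)
        if gmag.max() == 0:
            continue
        try:
            high = threshold_otsu(gmag)
        except ValueError:
            continue
        edges = canny(sl, low_threshold=canny_low_fraction * high,
                      high_threshold=high, use_quantiles=False)
        if not edges.any():
            continue
        strength = g2 if exponent == "squared" else gmag
        num += float(strength[edges].sum())
        den += float(edges.sum())
    if den == 0:
        raise NoEdgesError("no edges detected in any slice")
    return num / den


def normalized_sharpness(recon, ref, **kwargs) -> float:
    """AES of the reconstruction divided by AES of the reference."""
    return aes(recon, **kwargs) / aes(ref, **kwargs)


# ---------------------------------------------------------------------------
# tissue masks, SNR, CNR
# ---------------------------------------------------------------------------


@dataclass
class TissueMasks:
    """Per-voxel membership maps for GM/WM/CSF plus a background mask."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        for m in (self.gm, self.wm, self.csf):
            if m.min() < 0 or m.max() > 1:
                raise MetricError("membership probabilities must lie in [0,1]")
        tissue = (self.gm > 0) | (self.wm > 0) | (self.csf > 0)
        if np.any(tissue & (self.background > 0)):
            raise MetricError("background overlaps tissue support")

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "TissueMasks":
        """Labels: 0 background, 1 CSF, 2 GM, 3 WM."""
        return cls(
            gm=(labels == 2).astype(float),
            wm=(labels == 3).astype(float),
            csf=(labels == 1).astype(float),
            background=(labels == 0).astype(float),
        )


@dataclass
class TissueStats:
    s: float
    s_gm: float
    s_wm: float
    sigma_noise: float
    n_gm: int
    n_wm: int


def tissue_stats(vol, masks: TissueMasks) -> TissueStats:
    arr = _as_array(vol)
    gm = masks.gm > 0.5
    wm = masks.wm > 0.5
    bg = masks.background > 0.5
    if not bg.any():
        raise MetricError("empty background")
    n_gm, n_wm = int(gm.sum()), int(wm.sum())
    if n_gm + n_wm == 0:
        raise MetricError("no GM/WM voxels")
    s_gm = float(arr[gm].mean()) if n_gm else 0.0
    s_wm = float(arr[wm].mean()) if n_wm else 0.0
    s = (s_gm * n_gm + s_wm * n_wm) / (n_gm + n_wm)
    sigma = float(arr[bg].std())
    return TissueStats(s=s, s_gm=s_gm, s_wm=s_wm, sigma_noise=sigma,
                       n_gm=n_gm, n_wm=n_wm)


def snr(vol, masks: TissueMasks) -> float:
    """Count-weighted GM+WM mean over background standard deviation."""
    st = tissue_stats(vol, masks)
    if st.sigma_noise == 0:
        raise MetricError("zero background noise; SNR undefined")
    return st.s / st.sigma_noise


def cnr(vol, masks: TissueMasks) -> float:
    """|GM mean - WM mean| over background standard deviation."""
    st = tissue_stats(vol, masks)
    if st.sigma_noise == 0:
        raise MetricError("zero background noise; CNR undefined")
    return abs(st.s_gm - st.s_wm) / st.sigma_noise


def segment_simple(vol, contrast: str = "t2", seed: int = 0) -> TissueMasks:
    """Stand-in tissue segmenter: Otsu head mask + 3-class k-means.

    Background separates by Otsu threshold and largest connected component;
    the in-mask intensities are clustered into three classes mapped to
    CSF/GM/WM by mean rank under the stated contrast (T2: WM < GM < CSF;
    T1: CSF < GM < WM).
    """
    arr = _as_array(vol)
    if arr.max() == arr.min():
        raise MetricError("constant image cannot be segmented")
    thr = threshold_otsu(arr)
    fg = arr > thr * 0.5
    lab, n = ndimage.label(fg)
    if n == 0:
        raise MetricError("no foreground found")
    sizes = ndimage.sum(fg, lab, index=range(1, n + 1))
    head = lab == (1 + int(np.argmax(sizes)))
    head = ndimage.binary_fill_holes(head)
    vals = arr[head].reshape(-1, 1)
    if len(np.unique(vals)) < 3:
        raise MetricError("fewer than 3 separable intensity classes")
    km = KMeans(n_clusters=3, n_init=4, random_state=seed).fit(vals)
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)  # ascending mean intensity
    if contrast == "t2":
        cls_for = {"wm": order[0], "gm": order[1], "csf": order[2]}
    else:
        cls_for = {"csf": order[0], "gm": order[1], "wm": order[2]}
    assign = np.full(arr.shape, -1, dtype=int)
    assign[head] = km.labels_
    return TissueMasks(
        gm=(assign == cls_for["gm"]).astype(float),
        wm=(assign == cls_for["wm"]).astype(float),
        csf=(assign == cls_for["csf"]).astype(float),
        background=(~head).astype(float),
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a > 0.5
    b = b > 0.5
    denom = a.sum() + b.sum()
    if denom == 0:
        raise MetricError("empty masks")
    return 2.0 * float((a & b).sum()) / float(denom)


def metric_report(
    recon: Volume,
    reference: Volume | None = None,
    masks: TissueMasks | None = None,
    bins: int = 256,
) -> dict:
    """All applicable metrics for one reconstruction, as a plain dict."""
    out: dict = {}
    if reference is not None:
        out["ssim"] = ssim(recon, reference)
        rec = recon
        if recon.shape != reference.shape:
            rec = resample_to_lattice(
                recon, reference.spacing, reference.shape, "trilinear"
            )
        out["nmi"] = nmi(rec, reference, bins=bins)
        out["jsd"] = jsd(recon, reference, bins=bins)
        try:
            out["sharpness"] = normalized_sharpness(rec, reference)
        except NoEdgesError:
            out["sharpness"] = float("nan")
    if masks is not None:
        out["snr"] = snr(recon, masks)
        out["cnr"] = cnr(recon, masks)
    return out
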