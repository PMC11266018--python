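"""ROI time-series extraction, all-pairs directed-connectivity matrices,
magnitude-phase correlation diagnostics, and two-group edge-wise testing.

Per-ROI complex-valued series are formed by arithmetically averaging voxel
magnitudes and voxel phases within each atlas label at every time point
(phase averaging is arithmetic, not circular — the averaged phase series
is treated as an ordinary real series downstream, consistent with how the
estimators consume it).  Directed connectivity between every ROI pair is
the signed surrogate-corrected causality difference, giving an
antisymmetric matrix with a significance mask after Benjamini-Hochberg FDR
across all N(N-1)/2 edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .entropy import TEConfig
from .inference import FORWARD, delta_c
from .signals import ComplexSeries

__all__ = [
    "ROISeriesSet",
    "ConnectivityMatrix",
    "extract_roi_series",
    "ROIConnectivity",
    "magphase_correlation",
    "group_edge_test",
    "network_block_counts",
    "load_nifti_pair",
    "read_connectivity_csv",
    "write_connectivity_csv",
]

#: the ten canonical resting-state networks used to group the 116 atlas ROIs
NETWORK_NAMES = ("MV", "OPV", "LV", "DMN", "CER", "SEM", "TEM", "ADMN",
                 "LFP", "RFP")


@dataclass
class ROISeriesSet:
    """One subject's per-ROI complex-valued time series."""

    series: list
    roi_ids: list
    network_map: dict | None = None
    excluded: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.series) != len(self.roi_ids):
            raise ValueError("series/roi_ids length mismatch")
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("roi_ids must be unique")
        lengths = {s.T for s in self.series if s is not None}
        if len(lengths) > 1:
            raise ValueError("all ROI series must share the same length")

    @property
    def n_rois(self) -> int:
        return len(self.series)

    @property
    def T(self) -> int:
        for s in self.series:
            if s is not None:
                return s.T
        raise ValueError("no usable ROI series")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """N x N signed causality-difference matrix with significance mask.

    ``delta_c`` is antisymmetric with zero diagonal (entry [i, j] > 0 means
    inferred direction ROI_i -> ROI_j); ``p`` holds the per-edge p-values
    (symmetric); ``sig_mask`` marks edges surviving FDR.
    """

    delta_c: np.ndarray
    p: np.ndarray
    sig_mask: np.ndarray
    roi_ids: list

    def __post_init__(self):
        d = np.asarray(self.delta_c, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("delta_c must be square")
        if not np.allclose(d, -d.T, atol=1e-12) or np.any(np.diag(d) != 0):
            raise ValueError("delta_c must be antisymmetric with zero diagonal")
        object.__setattr__(self, "delta_c", d)

    @property
    def n_rois(self) -> int:
        return self.delta_c.shape[0]


def extract_roi_series(magnitude_4d, phase_4d, atlas_3d,
                       roi_ids=None) -> ROISeriesSet:
    """Average voxel magnitude and phase within each atlas label.

    ``magnitude_4d``/``phase_4d`` are (X, Y, Z, T) arrays on the same grid
    as the integer label volume ``atlas_3d`` (0 = background).  Empty ROIs
    yield all-NaN series, a warning, and an entry in ``excluded``.
    """
    mag = np.asarray(magnitude_4d, dtype=float)
    ph = np.asarray(phase_4d, dtype=float)
    atlas = np.asarray(atlas_3d)
    if mag.ndim != 4 or mag.shape != ph.shape:
        raise ValueError("magnitude/phase must be matching 4-D arrays")
    if atlas.shape != mag.shape[:3]:
        raise ValueError("atlas grid does not match the data volumes")
    if roi_ids is None:
        roi_ids = sorted(int(v) for v in np.unique(atlas) if v != 0)

    series, excluded = [], []
    for roi in roi_ids:
        mask = atlas == roi
        if not mask.any():
            warnings.warn(f"ROI {roi} has no voxels; excluded",
                          RuntimeWarning, stacklevel=2)
            excluded.append(roi)
            series.append(None)
            continue
        series.append(ComplexSeries(mag[mask].mean(axis=0),
                                    ph[mask].mean(axis=0), name=f"roi{roi}"))
    return ROISeriesSet(series, list(roi_ids), excluded=excluded)


class ROIConnectivity:
    """All-pairs directed-connectivity model for one subject's ROI set.

    fit() runs the shuffle-surrogate pipeline over every unordered ROI pair
    and assembles the antisymmetric causality-difference matrix; the
    significance mask applies BH-FDR across all tested edges.
    """

    def __init__(self, roi_set: ROISeriesSet, estimator: str = "cte",
                 config: TEConfig | None = None):
        self.roi_set = roi_set
        self.estimator = estimator
        self.config = config or TEConfig()

    def fit(self, R: int = 100, seed=0, q: float = 0.05,
            p_method: str = "ttest") -> ConnectivityMatrix:
        n = self.roi_set.n_rois
        dmat = np.zeros((n, n))
        pmat = np.ones((n, n))
        ss = np.random.SeedSequence(seed)
        pairs, pvals = [], []
        for i in range(n):
            for j in range(i + 1, n):
                zi = self.roi_set.series[i]
                zj = self.roi_set.series[j]
                if zi is None or zj is None:
                    continue
                res = delta_c(zi, zj, self.config, self.estimator, R=R,
                              rng_seed=ss.spawn(1)[0], p_method=p_method)
                dmat[i, j] = res.delta_c_mean
                dmat[j, i] = -res.delta_c_mean
                pmat[i, j] = pmat[j, i] = res.p_value
                pairs.append((i, j))
                pvals.append(res.p_value)
        sig = np.zeros((n, n), dtype=bool)
        if pvals:
            rej = multipletests(pvals, alpha=q, method="fdr_bh")[0]
            for (i, j), r in zip(pairs, rej):
                sig[i, j] = sig[j, i] = r
        return ConnectivityMatrix(dmat, pmat, sig, list(self.roi_set.roi_ids))


def magphase_correlation(subjects) -> np.ndarray:
    """Subject-averaged Pearson correlation between ROI m's magnitude and
    ROI n's phase, for all (m, n) including the diagonal.

    Constant series contribute correlation 0 (with a warning)."""
    subjects = list(subjects)
    if not subjects:
        raise ValueError("need at least one subject")
    n = subjects[0].n_rois
    acc = np.zeros((n, n))
    warned = False
    for sub in subjects:
        if sub.n_rois != n:
            raise ValueError("subjects must share the same ROI count")
        mags = np.array([s.magnitude for s in sub.series])
        phs = np.array([s.phase for s in sub.series])
        mags = mags - mags.mean(axis=1, keepdims=True)
        phs = phs - phs.mean(axis=1, keepdims=True)
        ms = mags.std(axis=1)
        ps = phs.std(axis=1)
        if (np.any(ms == 0) or np.any(ps == 0)) and not warned:
            warnings.warn("constant ROI series: correlation set to 0",
                          RuntimeWarning, stacklevel=2)
            warned = True
        denom = np.outer(ms, ps)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (mags @ phs.T) / (mags.shape[1] * denom)
        corr[denom == 0] = 0.0
        acc += corr
    return acc / len(subjects)


def group_edge_test(group1, group2, p_th: float = 0.05,
                    q: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Edge-wise two-sample t-test between two groups of connectivity
    matrices with BH-FDR across all upper-triangle edges.

    Returns ``(d, pvals)`` where ``d[n, m]`` carries the t-value on edges
    surviving FDR and 0 elsewhere (antisymmetric counterpart filled so the
    matrix reflects the signed edge orientation), and ``pvals`` holds raw
    per-edge p-values.  ``q`` defaults to ``p_th``.
    """
    group1 = list(group1)
    group2 = list(group2)
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("need at least 2 subjects per group")
    n = group1[0].n_rois
    for m in group1 + group2:
        if m.n_rois != n:
            raise ValueError("all matrices must share ROI count")
    q = p_th if q is None else q

    a = np.stack([m.delta_c for m in group1])   # (K1, N, N)
    b = np.stack([m.delta_c for m in group2])
    iu = np.triu_indices(n, k=1)
    tmat = np.zeros((n, n))
    pmat = np.ones((n, n))

    tvals, pvals = [], []
    for i, j in zip(*iu):
        x, y = a[:, i, j], b[:, i, j]
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            # exact-equality shortcut: identical constants are never a
            # group difference; distinct constants are a sure one
            if x[0] == y[0]:
                t, p = 0.0, 1.0
            else:
                t, p = (np.inf if x[0] > y[0] else -np.inf), 0.0
        else:
            t, p = stats.ttest_ind(x, y)
            t, p = float(t), float(p)
        tvals.append(t)
        pvals.append(p)
        pmat[i, j] = pmat[j, i] = p

    rej = multipletests(pvals, alpha=q, method="fdr_bh")[0]
    keep = rej & (np.array(pvals) < p_th)
    for (i, j), t, k in zip(zip(*iu), tvals, keep):
        if k:
            tmat[i, j] = t
            tmat[j, i] = -t
    return tmat, pmat


def network_block_counts(edge_matrix: np.ndarray, roi_ids,
                         network_map: dict) -> pd.DataFrame:
    """Aggregate significant edges into network-by-network counts.

    ``network_map`` maps ROI id -> network name; edges whose endpoint lacks
    a mapping are dropped.
    """
    nets = list(dict.fromkeys(network_map.values()))
    counts = pd.DataFrame(0, index=nets, columns=nets)
    n = len(roi_ids)
    for i in range(n):
        for j in range(n):
            if i == j or edge_matrix[i, j] == 0:
                continue
            ni = network_map.get(roi_ids[i])
            nj = network_map.get(roi_ids[j])
            if ni is None or nj is None:
                continue
            counts.loc[ni, nj] += 1
    return counts


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def load_nifti_pair(magnitude_path, phase_path, atlas_path) -> ROISeriesSet:
    """Load 4-D magnitude/phase volumes plus an integer atlas from NIfTI
    files and extract per-ROI series."""
    import nibabel as nib

    mag = np.asanyarray(nib.load(str(magnitude_path)).dataobj, dtype=float)
    ph = np.asanyarray(nib.load(str(phase_path)).dataobj, dtype=float)
    atlas = np.asanyarray(nib.load(str(atlas_path)).dataobj)
    return extract_roi_series(mag, ph, np.rint(atlas).astype(int))


def write_connectivity_csv(matrix: ConnectivityMatrix, path,
                           header_lines=None) -> None:
    """Long-format CSV: roi_i, roi_j, delta_c, p, sig for i < j."""
    rows = []
    ids = matrix.roi_ids
    for i in range(matrix.n_rois):
        for j in range(i + 1, matrix.n_rois):
            rows.append({
                "roi_i": ids[i], "roi_j": ids[j],
                "delta_c": matrix.delta_c[i, j],
                "p": matrix.p[i, j],
                "sig": bool(matrix.sig_mask[i, j]),
            })
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_connectivity_csv(path) -> ConnectivityMatrix:
    """Inverse of :func:`write_connectivity_csv`."""
    df = pd.read_csv(path, comment="#")
    ids = sorted(set(df["roi_i"]) | set(df["roi_j"]))
    idx = {r: k for k, r in enumerate(ids)}
    n = len(ids)
    d = np.zeros((n, n))
    p = np.ones((n, n))
    sig = np.zeros((n, n), dtype=bool)
    for _, row in df.iterrows():
        i, j = idx[row["roi_i"]], idx[row["roi_j"]]
        d[i, j] = row["delta_c"]
        d[j, i] = -row["delta_c"]
        p[i, j] = p[j, i] = row["p"]
        sig[i, j] = sig[j, i] = bool(row["sig"])
    return ConnectivityMatrix(d, p, sig, ids)
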