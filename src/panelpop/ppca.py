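"""Probabilistic PCA on incomplete dosage matrices.

EM for the latent-variable PCA model y = W x + eps (isotropic noise),
treating missing entries as latent. The exact per-sample E-step is used
(posterior over scores given each sample's observed coordinates), so the
observed-data log-likelihood is non-decreasing across iterations. After
convergence missing entries are imputed from the model and the final
scores/loadings are orthogonalized by an SVD of the completed matrix, which
reduces to classical PCA when no data are missing.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, chrom_sort_key


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_samples, q)
    loadings: np.ndarray  # (n_snps, q), unit-norm columns
    explained_variance_ratio: np.ndarray  # (q,)
    n_iter: int
    final_delta: float
    converged: bool
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    sample_ids: list | None = None
    snp_meta: pd.DataFrame | None = None  # chrom/pos per SNP when available


def _as_float_matrix(matrix) -> tuple[np.ndarray, list | None, pd.DataFrame | None]:
    if isinstance(matrix, GenotypeMatrix):
        y = matrix.dosages.astype(float)
        y[matrix.dosages == MISSING] = np.nan
        return y, matrix.sample_ids, matrix.snps[["chrom", "pos"]].copy()
    y = np.asarray(matrix, dtype=float)
    return y, None, None


def ppca_fit(
    matrix,
    q: int = 10,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
) -> PCAResult:
    """Fit probabilistic PCA by EM on an incomplete matrix.

    Parameters
    ----------
    matrix
        :class:`GenotypeMatrix` or a float array with NaN for missing.
    q
        Number of retained components; must satisfy q < min(n_samples, n_snps).
    tol
        Convergence threshold on the relative change of the observed-data
        log-likelihood.
    """
    y, sample_ids, snp_meta = _as_float_matrix(matrix)
    n, d = y.shape
    if q >= min(n, d):
        raise ValueError(f"q={q} must be < min(n_samples, n_snps) = {min(n, d)}")
    obs = ~np.isnan(y)
    if not obs.any(axis=0).all():
        raise ValueError("every SNP needs >= 1 observed value")
    if not obs.any(axis=1).all():
        raise ValueError("every sample needs >= 1 observed value")

    mu = np.nanmean(y, axis=0)
    yc = np.where(obs, y - mu, 0.0)
    m = obs.astype(float)

    rng = np.random.default_rng(seed)
    # SVD warm start on the zero-imputed matrix + seeded jitter
    k = min(q, min(n, d) - 1)
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    w = vt[:q].T * (s[:q] / np.sqrt(max(n - 1, 1)))
    w = w + 0.01 * rng.standard_normal(w.shape) * (np.abs(w).mean() + 1e-8)
    total_var = (yc**2).sum() / max(obs.sum() - 1, 1)
    ss = max(total_var - (w**2).sum() / d, 1e-6)

    n_obs_entries = obs.sum()
    o_i = obs.sum(axis=1)
    ydoty = (yc**2).sum(axis=1)
    eye = np.eye(q)

    loglik_trace = []
    prev_ll = -np.inf
    delta = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: per-sample posterior over latent scores
        c = np.einsum("da,nd,db->nab", w, m, w)  # (n, q, q)
        b = yc @ w  # (n, q); rows of yc are zero at missing entries
        a = ss * eye + c
        ex = np.linalg.solve(a, b[..., None])[..., 0]  # (n, q)
        cov = ss * np.linalg.solve(a, np.broadcast_to(eye, (n, q, q)))
        exx = cov + ex[:, :, None] * ex[:, None, :]

        # observed-data log-likelihood (Woodbury / determinant lemma)
        sign, logdet_a = np.linalg.slogdet(a / ss)
        quad = (ydoty - (b * ex).sum(axis=1)) / ss
        ll = -0.5 * float(
            (o_i * np.log(2 * np.pi * ss)).sum() + logdet_a.sum() + quad.sum()
        )
        loglik_trace.append(ll)

        # M-step
        ad = np.einsum("nd,nab->dab", m, exx)  # (d, q, q)
        cd = yc.T @ ex  # (d, q)
        w = np.linalg.solve(ad, cd[..., None])[..., 0]
        recon = ex @ w.T
        t3 = np.einsum("da,nab,db->nd", w, exx, w)
        ss = float(
            ((yc**2 - 2 * yc * recon).sum() + (t3 * m).sum()) / n_obs_entries
        )
        ss = max(ss, 1e-12)

        delta = abs(ll - prev_ll) / (abs(prev_ll) + 1e-300)
        if np.isfinite(prev_ll) and delta < tol:
            converged = True
            break
        prev_ll = ll

    # complete the matrix from the model and orthogonalize via SVD
    c = np.einsum("da,nd,db->nab", w, m, w)
    b = yc @ w
    ex = np.linalg.solve(ss * eye + c, b[..., None])[..., 0]
    ycomp = np.where(obs, yc, ex @ w.T)
    u, s, vt = np.linalg.svd(ycomp, full_matrices=False)
    scores = u[:, :q] * s[:q]
    loadings = vt[:q].T
    total = (ycomp**2).sum()
    evr = (s[:q] ** 2) / total if total > 0 else np.zeros(q)

    # sign convention: largest-|loading| entry positive per component
    for j in range(q):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=evr,
        n_iter=it,
        final_delta=float(delta),
        converged=converged,
        loglik_trace=np.array(loglik_trace),
        sample_ids=sample_ids,
        snp_meta=snp_meta,
    )


def top_loading_snps(
    result: PCAResult,
    component: int = 1,
    k: int = 300,
    gap_bp: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k SNPs by |loading| on one component, plus contiguous blocks.

    ``component`` is 1-based. Ties (and the ranking of equal loadings) break
    deterministically by genome order. Selected SNPs on the same chromosome
    within ``gap_bp`` of each other merge into reported blocks.

    Returns ``(ranked SNPs, blocks)`` data frames.
    """
    if result.snp_meta is None:
        raise ValueError("PCA result has no SNP metadata; fit from a GenotypeMatrix")
    if not 1 <= component <= result.loadings.shape[1]:
        raise ValueError(f"component {component} not in fitted range")
    load = result.loadings[:, component - 1]
    df = result.snp_meta.copy()
    df["loading"] = load
    df["abs_loading"] = np.abs(load)
    df["_rank"] = [chrom_sort_key(c) for c in df["chrom"]]
    if k > len(df):
        warnings.warn(f"k={k} exceeds SNP count {len(df)}; truncating", stacklevel=2)
        k = len(df)
    df = df.sort_values(
        by=["abs_loading", "_rank", "pos"], ascending=[False, True, True]
    ).drop(columns="_rank")
    top = df.head(k).copy()

    ordered = top.sort_values(
        by=["chrom", "pos"],
        key=lambda col: (
            col.map(lambda c: chrom_sort_key(c)[0]) if col.name == "chrom" else col
        ),
    )
    blocks = []
    cur = None
    for _, row in ordered.iterrows():
        if (
            cur is not None
            and row["chrom"] == cur["chrom"]
            and row["pos"] - cur["end"] <= gap_bp
        ):
            cur["end"] = int(row["pos"])
            cur["n_snps"] += 1
        else:
            if cur is not None:
                blocks.append(cur)
            cur = {
                "chrom": row["chrom"],
                "start": int(row["pos"]),
                "end": int(row["pos"]),
                "n_snps": 1,
            }
    if cur is not None:
        blocks.append(cur)
    return top, pd.DataFrame(blocks)


def cluster_support(
    result: PCAResult, labels, min_group: int = 3
) -> pd.DataFrame:
    """Nearest-centroid assignment in PC1-PC2 space and discordance flags.

    Centroids are computed per labeled group (labels equal to
    ``"unassigned"`` are assigned but contribute no centroid). Groups with
    fewer than ``min_group`` members are flagged low-confidence. This is a
    reporting aid: samples are flagged, never removed.
    """
    labels = np.asarray(labels, dtype=object)
    xy = result.scores[:, :2]
    groups = [g for g in pd.unique(labels) if g != "unassigned"]
    if len(groups) < 2:
        raise ValueError("need >= 2 labeled groups")
    centroids = {}
    low_conf = {}
    for g in groups:
        sel = labels == g
        centroids[g] = xy[sel].mean(axis=0)
        low_conf[g] = bool(sel.sum() < min_group)
    cent = np.array([centroids[g] for g in groups])
    dist = np.linalg.norm(xy[:, None, :] - cent[None, :, :], axis=2)
    assigned = np.array([groups[i] for i in dist.argmin(axis=1)], dtype=object)
    out = pd.DataFrame(
        {
            "label": labels,
            "assigned": assigned,
            "discordant": (labels != assigned) & (labels != "unassigned"),
            "low_confidence_group": [low_conf.get(g, False) for g in assigned],
        }
    )
    if result.sample_ids is not None:
        out.index = pd.Index(result.sample_ids, name="sample_id")
    return out
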