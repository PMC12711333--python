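"""f4-statistics with SNP-block jackknife and a two-way admixture estimator.

The f4-statistic for populations (A, B; C, D) is the average over SNPs of
(pA - pB)(pC - pD).  It is zero in expectation whenever (A, B) and (C, D)
are clades relative to each other ("treeness"), so a non-zero value is
evidence of correlated drift, i.e. gene flow.  Standard errors come from a
weighted delete-one block jackknife over contiguous genomic blocks, which
is robust to linkage disequilibrium between nearby SNPs.

The two-way admixture estimator models a target as alpha*Source1 +
(1-alpha)*Source2.  For every outgroup O the identity

    f4(base, O; target, S2) = alpha * f4(base, O; S1, S2)

holds exactly under the model, so alpha is estimated by regression through
the origin of the left-hand statistics on the right-hand ones across
outgroups.  The accompanying residual statistic is referred to a chi-square
distribution; it is a transparent approximation to the fit test of
likelihood-based admixture tools, not a replica of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .popsim import MISSING, AlleleFreqTable, GenotypeMatrix


@dataclass
class F4Result:
    """f4 estimate with block-jackknife uncertainty."""

    a: str
    b: str
    c: str
    d: str
    estimate: float
    se: float
    z: float
    n_snps: int
    n_blocks: int


@dataclass
class AdmixtureFit:
    """Two-way admixture fit: target = alpha*source1 + (1-alpha)*source2."""

    target: str
    source1: str
    source2: str
    base: str
    outgroups: list[str]
    alpha: float
    se: float
    fit_stat: float
    fit_p: float
    admissible: bool
    n_snps: int
    n_blocks: int


def assign_blocks(snps: pd.DataFrame, block_size_cm: float = 5.0) -> np.ndarray:
    """Contiguous jackknife block ids from cM positions.

    ``snps`` needs ``chrom`` and ``cm`` columns sorted by position within
    each chromosome.  Blocks are at most ``block_size_cm`` wide and never
    span chromosomes.
    """
    if block_size_cm <= 0:
        raise ValueError("block_size_cm must be positive")
    chrom = snps["chrom"].to_numpy()
    cm = snps["cm"].to_numpy(dtype=float)
    ids = np.empty(len(snps), dtype=int)
    offset = 0
    for ch in pd.unique(chrom):
        mask = chrom == ch
        pos = cm[mask]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"SNP positions unsorted within chromosome {ch!r}")
        local = np.floor(pos / block_size_cm).astype(int)
        # re-index to contiguous ids per chromosome
        _, dense = np.unique(local, return_inverse=True)
        ids[mask] = offset + dense
        offset = ids[mask].max() + 1
    return ids


def pop_freqs(gm: GenotypeMatrix, populations: list[str] | None = None) -> AlleleFreqTable:
    """Per-population allele frequencies from a genotype matrix.

    Frequency = mean non-missing call / 2.  SNPs with zero non-missing calls
    in a population get NaN there (flagged unusable for any f4 involving it).
    """
    pops = populations or sorted(set(gm.populations))
    pop_arr = np.asarray(gm.populations)
    cols = {}
    for pop in pops:
        idx = np.flatnonzero(pop_arr == pop)
        if idx.size == 0:
            raise ValueError(f"population {pop!r} has no individuals")
        sub = gm.calls[:, idx].astype(float)
        sub[sub == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN SNP -> NaN
            cols[pop] = np.nanmean(sub, axis=1) / 2.0
    return AlleleFreqTable(snps=gm.snps.copy(), freqs=pd.DataFrame(cols))


def jackknife(block_stats: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Weighted delete-one-block jackknife.

    ``block_stats`` are per-block means of a statistic, ``weights`` the
    number of observations per block.  Returns (estimate, SE) where the
    estimate is the weighted mean over blocks and the SE follows the
    standard weighted-jackknife variance formula (which reduces to the
    ordinary delete-one jackknife for equal weights).
    """
    theta_b = np.asarray(block_stats, dtype=float)
    w = np.asarray(weights, dtype=float)
    if theta_b.shape != w.shape:
        raise ValueError("block_stats and weights must have the same shape")
    keep = w > 0
    theta_b, w = theta_b[keep], w[keep]
    g = theta_b.size
    if g < 2:
        raise ValueError("jackknife needs at least 2 non-empty blocks")
    n = w.sum()
    total = (w * theta_b).sum()
    est = total / n
    loo = (total - w * theta_b) / (n - w)  # delete-one estimates
    return est, _loo_se(est, loo, w)


def _loo_se(theta_full: float, loo: np.ndarray, weights: np.ndarray) -> float:
    """Weighted-jackknife SE from delete-one-block estimates.

    Uses the pseudovalue form with h_j = n / m_j; for equal block weights it
    reduces to the ordinary delete-one jackknife SE.
    """
    loo = np.asarray(loo, dtype=float)
    w = np.asarray(weights, dtype=float)
    g = loo.size
    n = w.sum()
    h = n / w
    theta_jack = g * theta_full - ((1.0 - w / n) * loo).sum()
    tau = h * theta_full - (h - 1.0) * loo  # pseudovalues
    var = ((tau - theta_jack) ** 2 / (h - 1.0)).sum() / g
    return float(np.sqrt(var))


def _usable(freqs: AlleleFreqTable, pops: list[str]) -> np.ndarray:
    sub = freqs.freqs[pops].to_numpy(dtype=float)
    return ~np.isnan(sub).any(axis=1)


def _blocks(freqs: AlleleFreqTable, blocks: np.ndarray | None) -> np.ndarray:
    if blocks is not None:
        return np.asarray(blocks, dtype=int)
    if "block" in freqs.snps.columns:
        return freqs.snps["block"].to_numpy(dtype=int)
    return assign_blocks(freqs.snps)


def f4(
    freqs: AlleleFreqTable,
    a: str,
    b: str,
    c: str,
    d: str,
    blocks: np.ndarray | None = None,
) -> F4Result:
    """f4(A, B; C, D) with block-jackknife SE.

    SNPs missing (NaN) in any of the four populations are excluded
    (complete-case).  Requires >= 2 non-empty blocks.
    """
    for pop in (a, b, c, d):
        if pop not in freqs.freqs.columns:
            raise ValueError(f"population {pop!r} not in frequency table")
    blk = _blocks(freqs, blocks)
    use = _usable(freqs, [a, b, c, d])
    f = freqs.freqs
    prod = (
        (f[a].to_numpy() - f[b].to_numpy()) * (f[c].to_numpy() - f[d].to_numpy())
    )[use]
    blk = blk[use]
    if prod.size == 0:
        raise ValueError("no usable SNPs for this f4")
    order = np.argsort(blk, kind="stable")
    blk, prod = blk[order], prod[order]
    uniq, idx = np.unique(blk, return_index=True)
    if uniq.size < 2:
        raise ValueError("fewer than 2 usable jackknife blocks; SE undefined")
    sums = np.add.reduceat(prod, idx)
    counts = np.diff(np.append(idx, prod.size))
    est, se = jackknife(sums / counts, counts)
    z = est / se if se > 0 else 0.0
    return F4Result(a, b, c, d, est, se, float(z), int(prod.size), int(uniq.size))


def f4_profile(
    freqs: AlleleFreqTable,
    targets: list[str],
    ref1: str,
    ref2: str,
    base: str,
    blocks: np.ndarray | None = None,
    z_threshold: float = 3.0,
) -> pd.DataFrame:
    """f4(base, target; ref1, ref2) for every target, with an affinity call.

    Shared drift between the target and ref1 drives the statistic negative
    (the target term enters with a minus sign), so estimate < 0 with
    |Z| >= ``z_threshold`` is called "ref1", the mirror case "ref2", and
    |Z| below the threshold "non-significant" — the convention of plotting
    such scans with a band at |Z| < 3.
    """
    rows = []
    for t in targets:
        r = f4(freqs, base, t, ref1, ref2, blocks=blocks)
        if abs(r.z) < z_threshold:
            call = "non-significant"
        else:
            call = ref1 if r.z < 0 else ref2
        rows.append(
            {
                "target": t, "ref1": ref1, "ref2": ref2, "base": base,
                "estimate": r.estimate, "se": r.se, "z": r.z,
                "n_snps": r.n_snps, "n_blocks": r.n_blocks, "affinity": call,
            }
        )
    return pd.DataFrame(rows)


def admix_two_way(
    freqs: AlleleFreqTable,
    target: str,
    source1: str,
    source2: str,
    outgroups: list[str],
    base: str,
    blocks: np.ndarray | None = None,
) -> AdmixtureFit:
    """Estimate the two-way admixture proportion alpha for the target.

    For each outgroup O: x = f4(base, O; target, source2) and
    y = f4(base, O; source1, source2); alpha minimises sum (x - alpha*y)^2.
    The SE is a delete-one-block jackknife of the whole fit.  The residual
    statistic sums squared standardised residuals and is referred to
    chi-square with (n_outgroups - 1) degrees of freedom — an approximation,
    flagged as such in the output schema.  alpha is reported even outside
    [0, 1]; the ``admissible`` flag records whether it is a proportion.
    """
    if len(outgroups) < 2:
        raise ValueError("need at least 2 outgroups")
    pops = [base, target, source1, source2, *outgroups]
    for pop in pops:
        if pop not in freqs.freqs.columns:
            raise ValueError(f"population {pop!r} not in frequency table")
    blk = _blocks(freqs, blocks)
    use = _usable(freqs, pops)
    f = freqs.freqs
    pb = f[base].to_numpy()[use]
    pt = f[target].to_numpy()[use]
    p1 = f[source1].to_numpy()[use]
    p2 = f[source2].to_numpy()[use]
    blk = blk[use]
    if blk.size == 0:
        raise ValueError("no usable SNPs for the admixture fit")

    og = np.column_stack([f[o].to_numpy()[use] for o in outgroups])
    d_base = pb[:, None] - og  # (n_snps, n_og)
    x = d_base * (pt - p2)[:, None]
    y = d_base * (p1 - p2)[:, None]

    order = np.argsort(blk, kind="stable")
    blk, x, y = blk[order], x[order], y[order]
    uniq, idx = np.unique(blk, return_index=True)
    if uniq.size < 2:
        raise ValueError("fewer than 2 usable jackknife blocks")
    counts = np.diff(np.append(idx, blk.size)).astype(float)
    xs = np.add.reduceat(x, idx, axis=0)  # per-block sums (n_blocks, n_og)
    ys = np.add.reduceat(y, idx, axis=0)
    n = counts.sum()
    x_full = xs.sum(axis=0) / n  # per-outgroup f4 estimates
    y_full = ys.sum(axis=0) / n

    # diagnose indistinguishable sources: joint test of y == 0 across outgroups
    y_se = y.std(axis=0, ddof=1) / np.sqrt(n)
    y_z = y_full / np.maximum(y_se, 1e-300)
    if (y_z**2).sum() < stats.chi2.isf(1e-3, len(outgroups)):
        raise ValueError(
            "sources are indistinguishable to the chosen outgroups "
            "(all f4(base, O; source1, source2) consistent with 0)"
        )

    def fit_alpha(xv: np.ndarray, yv: np.ndarray) -> float:
        return float(xv @ yv / (yv @ yv))

    alpha = fit_alpha(x_full, y_full)

    # delete-one-block re-fits of the whole regression
    alphas, resids = [], []
    for j in range(uniq.size):
        xj = (xs.sum(axis=0) - xs[j]) / (n - counts[j])
        yj = (ys.sum(axis=0) - ys[j]) / (n - counts[j])
        aj = fit_alpha(xj, yj)
        alphas.append(aj)
        resids.append(xj - aj * yj)
    alpha_loo = np.asarray(alphas)
    alpha_se = _loo_se(alpha, alpha_loo, counts)

    r_full = x_full - alpha * y_full
    r_loo = np.asarray(resids)  # (n_blocks, n_og)
    r_se = np.array(
        [_loo_se(r_full[k], r_loo[:, k], counts) for k in range(len(outgroups))]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        std = np.where(r_se > 0, r_full / r_se, 0.0)
    fit_stat = float((std**2).sum())
    dof = len(outgroups) - 1
    fit_p = float(stats.chi2.sf(fit_stat, dof)) if dof > 0 else float("nan")

    return AdmixtureFit(
        target=target,
        source1=source1,
        source2=source2,
        base=base,
        outgroups=list(outgroups),
        alpha=alpha,
        se=alpha_se,
        fit_stat=fit_stat,
        fit_p=fit_p,
        admissible=bool(0.0 <= alpha <= 1.0),
        n_snps=int(n),
        n_blocks=int(uniq.size),
    )
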