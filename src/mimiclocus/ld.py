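"""Composite (Burrows) linkage disequilibrium for unphased diploid genotypes.

The composite disequilibrium coefficient sums the gametic and non-gametic
allele associations and is estimable from genotype dosages alone, with no
phase information:

    delta_hat = (sum_i x_i y_i) / (2n) - 2 p_x p_y

where x, y are alt-allele dosages and p the alt-allele frequencies over the
n pairwise-complete individuals.  The composite correlation divides by
within-locus Hardy-Weinberg disequilibrium-adjusted variances:

    r = delta_hat / sqrt((p_x q_x + D_x)(p_y q_y + D_y)),
    D = P(hom-alt) - p^2.

Pairs undefined (a site monomorphic in the pairwise-complete set, or a zero
denominator) are flagged, never raised.  Permutation significance shuffles
whole-individual genotypes at one site, preserving within-locus genotype
frequencies, which matches the unknown-phase setting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from mimiclocus.core_io import MISSING, DataError, GenotypeMatrix, VariantSite


def _prep(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("dosage vectors must cover the same individuals")
    ok = (x != MISSING) & (y != MISSING) & ~np.isnan(x) & ~np.isnan(y)
    return x[ok], y[ok]


def composite_delta(x, y) -> float:
    """Composite disequilibrium delta_hat; NaN when either site is
    monomorphic among the pairwise-complete individuals."""
    x, y = _prep(x, y)
    n = x.size
    if n == 0:
        return float("nan")
    px = x.mean() / 2.0
    py = y.mean() / 2.0
    if not (0.0 < px < 1.0 and 0.0 < py < 1.0):
        return float("nan")  # monomorphic in the pairwise-complete set
    return float((x * y).sum() / (2.0 * n) - 2.0 * px * py)


def composite_r(x, y) -> float:
    """Composite correlation r (signed); NaN when undefined."""
    x, y = _prep(x, y)
    n = x.size
    if n == 0:
        return float("nan")
    px, py = x.mean() / 2.0, y.mean() / 2.0
    if not (0.0 < px < 1.0 and 0.0 < py < 1.0):
        return float("nan")
    delta = (x * y).sum() / (2.0 * n) - 2.0 * px * py
    dx = (x == 2).mean() - px**2
    dy = (y == 2).mean() - py**2
    denom = (px * (1 - px) + dx) * (py * (1 - py) + dy)
    if denom <= 0:
        return float("nan")
    return float(delta / np.sqrt(denom))


def composite_r2(x, y) -> float:
    """Squared composite correlation, clamped to [0, 1]; NaN when undefined."""
    r = composite_r(x, y)
    if np.isnan(r):
        return r
    return float(min(1.0, r * r))


@dataclass
class LDMatrix:
    sites: list[VariantSite]
    delta: np.ndarray
    r: np.ndarray
    r2: np.ndarray
    p_perm: np.ndarray
    significant: np.ndarray  # Bonferroni mask over defined pairs
    defined: np.ndarray
    n_perm: int
    alpha: float

    @property
    def n_defined_pairs(self) -> int:
        iu = np.triu_indices(len(self.sites), k=1)
        return int(self.defined[iu].sum())


def ld_matrix(
    g: GenotypeMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> LDMatrix:
    """All-pairs composite LD with permutation significance.

    Missing data are handled by pairwise-complete deletion.  For each pair
    the later site's genotypes are shuffled across individuals ``n_perm``
    times; p = (1 + #{delta_perm^2 >= delta_obs^2}) / (n_perm + 1).  Because
    shuffling a whole site leaves both sites' genotype margins unchanged,
    delta^2 and r^2 order permutations identically, so the test on delta^2
    is the test on the allelic correlation.  Bonferroni significance is
    assessed over the number of defined pairs.
    """
    n_sites = g.n_sites
    if n_sites < 2:
        raise DataError("need at least 2 sites for an LD matrix")
    rng = np.random.default_rng([seed, 0x1D])
    X = g.dosage.astype(float)
    X[g.dosage == MISSING] = np.nan
    n_ind = X.shape[0]

    delta = np.full((n_sites, n_sites), np.nan)
    r = np.full((n_sites, n_sites), np.nan)
    p_perm = np.full((n_sites, n_sites), np.nan)

    complete = not np.isnan(X).any()
    if complete:
        p = X.mean(axis=0) / 2.0
        poly = (p > 0.0) & (p < 1.0)
        cross = X.T @ X / (2.0 * n_ind)
        delta = cross - 2.0 * np.outer(p, p)
        dw = (X == 2).mean(axis=0) - p**2
        denom = p * (1 - p) + dw
        scale = np.sqrt(np.outer(denom, denom))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(scale > 0, delta / scale, np.nan)
        bad = ~poly
        delta[bad, :] = np.nan
        delta[:, bad] = np.nan
        r[bad, :] = np.nan
        r[:, bad] = np.nan
        # permutation p-values: site j permuted against all earlier sites
        for j in range(1, n_sites):
            if not poly[j]:
                continue
            perm_idx = rng.permuted(
                np.tile(np.arange(n_ind), (n_perm, 1)), axis=1
            )
            perms = X[:, j][perm_idx]  # (n_perm, n_ind)
            d_perm = perms @ X[:, :j] / (2.0 * n_ind) - 2.0 * p[j] * p[:j]
            obs2 = delta[j, :j] ** 2
            count = (d_perm**2 >= obs2[None, :] - 1e-15).sum(axis=0)
            pj = (1.0 + count) / (n_perm + 1.0)
            pj[~poly[:j]] = np.nan
            p_perm[j, :j] = pj
            p_perm[:j, j] = pj
    else:
        for j in range(1, n_sites):
            for i in range(j):
                xi, yj = X[:, i], X[:, j]
                d = composite_delta(xi, yj)
                delta[i, j] = delta[j, i] = d
                rv = composite_r(xi, yj)
                r[i, j] = r[j, i] = rv
                if np.isnan(d):
                    continue
                ok = ~np.isnan(xi) & ~np.isnan(yj)
                xs, ys = xi[ok], yj[ok]
                count = 0
                for _ in range(n_perm):
                    dp = composite_delta(xs, rng.permutation(ys))
                    if not np.isnan(dp) and dp * dp >= d * d - 1e-15:
                        count += 1
                p_perm[i, j] = p_perm[j, i] = (1.0 + count) / (n_perm + 1.0)

    np.fill_diagonal(delta, [composite_delta(X[:, j], X[:, j]) for j in range(n_sites)])
    np.fill_diagonal(r, [composite_r(X[:, j], X[:, j]) for j in range(n_sites)])

    r2 = np.clip(r**2, 0.0, 1.0)
    defined = ~np.isnan(delta)
    iu = np.triu_indices(n_sites, k=1)
    n_pairs = int((defined[iu] & ~np.isnan(p_perm[iu])).sum())
    significant = np.zeros_like(delta, dtype=bool)
    if n_pairs:
        with np.errstate(invalid="ignore"):
            significant = p_perm <= alpha / n_pairs
        significant &= ~np.isnan(p_perm)
    return LDMatrix(
        sites=list(g.sites),
        delta=delta,
        r=r,
        r2=r2,
        p_perm=p_perm,
        significant=significant,
        defined=defined,
        n_perm=n_perm,
        alpha=alpha,
    )


def write_ld_tables(ldm: LDMatrix, outdir: str | Path, prefix: str = "ld") -> None:
    """Write delta, r2 and permutation-p matrices as TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = [f"{s.locus_id}:{s.pos}" for s in ldm.sites]
    for name, mat in (("delta", ldm.delta), ("r2", ldm.r2), ("p", ldm.p_perm)):
        pd.DataFrame(mat, index=labels, columns=labels).to_csv(
            outdir / f"{prefix}_{name}.tsv", sep="\t", float_format="%.6g"
        )


def plot_ld_heatmap(ldm: LDMatrix, path: str | Path) -> None:
    """Grey-scale r^2 heat map showing only Bonferroni-significant pairs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = np.where(ldm.significant, ldm.r2, np.nan)
    np.fill_diagonal(shown, 1.0)
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(shown, cmap="Greys", vmin=0, vmax=1, interpolation="nearest")
    fig.colorbar(im, ax=ax, label=r"$r^2$ (Bonferroni-significant pairs)")
    ax.set_xlabel("site index")
    ax.set_ylabel("site index")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
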