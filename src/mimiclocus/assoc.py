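"""Dominance-hierarchy-aware genotype-phenotype association scan.

Each morph of rank >= 1 is tested as cases against the pooled individuals of
all strictly lower-ranked morphs, reflecting the genetics of a dominance
hierarchy: an allele diagnostic for a morph may legitimately be carried
(recessively, usually heterozygously) by higher-ranked morphs, but can never
appear in lower-ranked ones.

Per site the genotypes are collapsed into a 2x2 genotype-group x phenotype
table under a selectable genetic model, tested with the likelihood-ratio
(G) statistic, and assigned a permutation p-value with the add-one
convention.  Bonferroni correction is applied per morph over the sites
actually tested for that morph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from mimiclocus.core_io import (
    MISSING,
    DataError,
    GenotypeMatrix,
    MorphTable,
    VariantSite,
)

#: Available genetic models for collapsing genotypes.
#: - "recessive": {hom-major, het} vs {hom-minor} -- the minor allele must be
#:   homozygous to be exposed.
#: - "dominant": {hom-major} vs {het, hom-minor} -- minor-allele carriage.
#: - "allelic": allele-count 2x2 over chromosomes.
CODINGS = ("recessive", "dominant", "allelic")


class DegenerateTableError(DataError):
    """A 2x2 table with a zero margin; the site is untestable."""


@dataclass
class ResponseVector:
    focal_morph: str
    case_ids: list[str]
    control_ids: list[str]

    def __post_init__(self) -> None:
        if set(self.case_ids) & set(self.control_ids):
            raise DataError("case and control sets overlap")


@dataclass
class AssocResult:
    site: VariantSite
    focal_morph: str
    table: np.ndarray | None
    G: float
    p_perm: float
    p_bonf: float
    n_perm: int
    tested: bool = True
    flag: str = ""


@dataclass
class FullAssociation:
    """An allele carried by every focal-morph individual and by no
    lower-ranked individual.  Carriage in higher-ranked morphs is listed,
    never disqualifying (it marks hidden recessive alleles)."""

    site: VariantSite
    allele: str
    morph: str
    carriage_above: list[str] = field(default_factory=list)


def build_response(m: MorphTable, focal: str) -> ResponseVector:
    """Cases = focal-morph individuals; controls = all lower-ranked morphs."""
    if focal not in m.rank_of:
        raise DataError(f"unknown morph {focal!r}")
    rank = m.rank_of[focal]
    if rank == 0:
        raise DataError(f"no lower morphs below bottom-recessive {focal!r}")
    cases = [i for i, mo in m.morph_of.items() if mo == focal]
    controls = [i for i, mo in m.morph_of.items() if m.rank_of[mo] < rank]
    return ResponseVector(focal_morph=focal, case_ids=cases, control_ids=controls)


# ---------------------------------------------------------------------------
# Tables and the G statistic


def _minor_dosage(dosages: np.ndarray, minor_is_alt: bool) -> np.ndarray:
    d = np.asarray(dosages)
    out = d.copy()
    if not minor_is_alt:
        out[d != MISSING] = 2 - d[d != MISSING]
    return out


def genotype_table(
    dosages: Sequence[int],
    case_mask: Sequence[bool],
    coding: str = "recessive",
    minor_is_alt: bool = True,
) -> np.ndarray:
    """Collapse genotypes into a 2x2 table (genotype group x case/control).

    Rows are the two genotype groups under ``coding`` (unexposed first),
    columns are (cases, controls).  Missing genotypes are dropped.  For
    ``allelic`` the rows are (major allele, minor allele) chromosome counts.
    """
    if coding not in CODINGS:
        raise DataError(f"unknown coding {coding!r}; choose from {CODINGS}")
    d = np.asarray(dosages)
    cases = np.asarray(case_mask, dtype=bool)
    called = d != MISSING
    if not (called & cases).any() or not (called & ~cases).any():
        raise DegenerateTableError("a phenotype group is entirely missing")
    md = _minor_dosage(d, minor_is_alt)
    n_case = int((called & cases).sum())
    n_ctrl = int((called & ~cases).sum())
    if coding == "allelic":
        minor_case = int(md[called & cases].sum())
        minor_ctrl = int(md[called & ~cases].sum())
        table = np.array(
            [
                [2 * n_case - minor_case, 2 * n_ctrl - minor_ctrl],
                [minor_case, minor_ctrl],
            ]
        )
    else:
        exposed = (md == 2) if coding == "recessive" else (md >= 1)
        exp_case = int((exposed & called & cases).sum())
        exp_ctrl = int((exposed & called & ~cases).sum())
        table = np.array(
            [
                [n_case - exp_case, n_ctrl - exp_ctrl],
                [exp_case, exp_ctrl],
            ]
        )
    return table


def lrt_statistic(table: np.ndarray) -> float:
    """G = 2 sum O ln(O/E) over the 2x2 cells, with 0 ln(0/E) == 0.

    Raises :class:`DegenerateTableError` when a row or column margin is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise DataError(f"expected a 2x2 table, got shape {t.shape}")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise DegenerateTableError("degenerate table (zero margin)")
    expected = np.outer(rows, cols) / t.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(t > 0, t * np.log(t / expected), 0.0)
    return float(2.0 * terms.sum())


def _g_binary_support(n_case: int, n_ctrl: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """G values for every achievable exposed-in-cases count ``k``.

    Margins (n_case, n_ctrl; m exposed, n-m unexposed) are fixed under label
    permutation, so the permuted table -- hence G -- is a function of k alone.
    """
    n = n_case + n_ctrl
    k = np.arange(max(0, m - n_ctrl), min(m, n_case) + 1)
    t = np.stack(
        [n_case - k, n_ctrl - (m - k), k, m - k], axis=1
    ).reshape(-1, 2, 2).astype(float)
    rows = t.sum(axis=2, keepdims=True)
    cols = t.sum(axis=1, keepdims=True)
    expected = rows * cols / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(t > 0, t * np.log(t / expected), 0.0)
    return k, 2.0 * terms.sum(axis=(1, 2))


def permutation_pvalue(
    dosages: Sequence[int],
    case_mask: Sequence[bool],
    coding: str = "recessive",
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Permutation p-value for the G statistic of one site.

    Phenotype labels are permuted uniformly among called individuals.
    Because the table margins are fixed under permutation, the permuted
    exposed-in-cases cell follows its exact permutation distribution --
    hypergeometric for the genotype-group codings, and a dosage-weighted
    multivariate hypergeometric for the allelic coding -- which is sampled
    directly instead of materializing label shuffles.  Ties
    (G_perm == G_obs) count as >= (conservative), and the add-one estimator
    p = (1 + #{G_perm >= G_obs}) / (n_perm + 1) never returns 0.

    Returns ``(p, G_obs, table)``.
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    d = np.asarray(dosages)
    cases = np.asarray(case_mask, dtype=bool)
    called = d != MISSING
    d, cases = d[called], cases[called]
    table = genotype_table(d, cases, coding=coding)
    g_obs = lrt_statistic(table)  # raises DegenerateTableError when untestable

    n_case = int(cases.sum())
    n_ctrl = int((~cases).sum())
    if coding == "allelic":
        counts = np.array([(d == 0).sum(), (d == 1).sum(), (d == 2).sum()])
        draws = rng.multivariate_hypergeometric(counts, n_case, size=n_perm)
        minor_case = draws[:, 1] + 2 * draws[:, 2]
        m = int(d.sum())
        support, g_vals = _g_binary_support(2 * n_case, 2 * n_ctrl, m)
        g_perm = g_vals[np.searchsorted(support, minor_case)]
    else:
        exposed = table[1, 0] + table[1, 1]
        k_perm = rng.hypergeometric(exposed, n_case + n_ctrl - exposed, n_case, size=n_perm)
        support, g_vals = _g_binary_support(n_case, n_ctrl, int(exposed))
        g_perm = g_vals[np.searchsorted(support, k_perm)]
    p = (1.0 + int((g_perm >= g_obs).sum())) / (n_perm + 1.0)
    return p, g_obs, table


# ---------------------------------------------------------------------------
# Scanning


@dataclass
class ScanConfig:
    coding: str = "recessive"
    n_perm: int = 999
    seed: int = 0
    alpha: float = 0.05


def scan(g: GenotypeMatrix, m: MorphTable, cfg: ScanConfig | None = None) -> list[AssocResult]:
    """Association scan of every site against every morph of rank >= 1.

    Untestable sites (degenerate tables) are flagged, not aborted, and are
    excluded from that morph's Bonferroni multiplier.
    """
    cfg = cfg or ScanConfig()
    minor_alt = _minor_is_alt(g)
    results: list[AssocResult] = []
    case_masks = {}
    for morph in m.hierarchy[1:]:
        resp = build_response(m, morph)
        in_test = set(resp.case_ids) | set(resp.control_ids)
        idx = [i for i, ind in enumerate(g.individuals) if ind in in_test]
        mask = np.array([g.individuals[i] in set(resp.case_ids) for i in idx])
        case_masks[morph] = (np.array(idx, dtype=int), mask)

    for rank, morph in enumerate(m.hierarchy):
        if rank == 0:
            continue
        idx, mask = case_masks[morph]
        rng = np.random.default_rng([cfg.seed, rank])
        morph_results: list[AssocResult] = []
        for j, site in enumerate(g.sites):
            d = _minor_dosage(g.dosage[idx, j], minor_alt[j])
            try:
                p, g_obs, table = permutation_pvalue(
                    d, mask, coding=cfg.coding, n_perm=cfg.n_perm, rng=rng
                )
                morph_results.append(
                    AssocResult(site, morph, table, g_obs, p, np.nan, cfg.n_perm)
                )
            except DegenerateTableError as exc:
                morph_results.append(
                    AssocResult(
                        site, morph, None, np.nan, np.nan, np.nan, cfg.n_perm,
                        tested=False, flag=str(exc),
                    )
                )
        n_tested = sum(r.tested for r in morph_results)
        for r in morph_results:
            if r.tested:
                r.p_bonf = min(1.0, r.p_perm * n_tested)
        results.extend(morph_results)
    return results


def _minor_is_alt(g: GenotypeMatrix) -> np.ndarray:
    """Per-site flag: True when the alt allele is the minor allele.

    At an exact 0.5/0.5 tie the ref allele is deemed major, so the alt
    allele is minor.
    """
    out = np.zeros(g.n_sites, dtype=bool)
    for j in range(g.n_sites):
        col = g.dosage[:, j]
        called = col != MISSING
        if not called.any():
            raise DataError(f"all genotypes missing at site index {j}")
        p_alt = col[called].sum() / (2.0 * called.sum())
        out[j] = p_alt <= 0.5
    return out


def results_to_frame(results: list[AssocResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "morph": r.focal_morph,
                "chrom": r.site.chrom,
                "pos": r.site.pos,
                "locus": r.site.locus_id,
                "G": r.G,
                "p_perm": r.p_perm,
                "p_bonf": r.p_bonf,
                "n_perm": r.n_perm,
                "tested": r.tested,
                "flag": r.flag,
            }
        )
    return pd.DataFrame(rows)


def top_site_per_morph(results: list[AssocResult]) -> dict[str, AssocResult]:
    """Most-associated tested site per morph: minimum p, ties broken by G.

    Permutation p-values floor at 1/(n_perm + 1), so perfectly associated
    sites tie there; the larger G identifies the more extreme table.
    """
    best: dict[str, AssocResult] = {}
    for r in results:
        if not r.tested:
            continue
        cur = best.get(r.focal_morph)
        if cur is None or (r.p_perm, -r.G) < (cur.p_perm, -cur.G):
            best[r.focal_morph] = r
    return best


# ---------------------------------------------------------------------------
# Full association


def full_association(g: GenotypeMatrix, m: MorphTable) -> list[FullAssociation]:
    """Alleles present (>= 1 copy) in every focal-morph individual and in
    zero copies in every lower-ranked individual, for each morph of rank >= 1.

    Higher-ranked carriers are reported in ``carriage_above``; they indicate
    a recessive focal-morph allele hidden by dominance.  Missing genotypes
    are excluded from the carrier conditions (pairwise deletion).
    """
    ranks = m.ranks_for(g.individuals)
    out: list[FullAssociation] = []
    for morph in m.hierarchy[1:]:
        rank = m.rank_of[morph]
        focal = ranks == rank
        lower = ranks < rank
        higher = ranks > rank
        for j, site in enumerate(g.sites):
            col = g.dosage[:, j]
            called = col != MISSING
            if not (focal & called).any() or not (lower & called).any():
                continue
            for allele, carrier in (
                (site.alt_allele, col >= 1),
                (site.ref_allele, (col <= 1) & called),
            ):
                carrier = carrier & called
                if not carrier[focal & called].all():
                    continue
                if carrier[lower & called].any():
                    continue
                above = [
                    g.individuals[i]
                    for i in np.flatnonzero(higher & carrier)
                ]
                out.append(FullAssociation(site, allele, morph, above))
    return out
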