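"""End-to-end reproducible pipeline: simulate -> filter -> association ->
LD -> duplication windows -> MK/HKA -> pedigree -> synteny -> report.

Every stage draws from a named substream of the root seed, all outputs are
written deterministically (sorted keys, fixed column order), and re-running
with the same configuration and seed reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from mimiclocus import assoc as assoc_mod
from mimiclocus import ld as ld_mod
from mimiclocus import mapping as mapping_mod
from mimiclocus import molevol as molevol_mod
from mimiclocus import structvar as structvar_mod
from mimiclocus.core_io import (
    DataError,
    GenotypeMatrix,
    filter_by_major_allele,
    write_genotypes,
)
from mimiclocus.simulate import SimConfig, simulate_brood, simulate_outgroup_coding, simulate_population, simulate_reads

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "assoc", "ld", "structvar", "molevol", "pedigree", "synteny")

#: 24 genes of the candidate interval, in map order; identical in the three
#: compared genomes (the interval shows full synteny).
CANDIDATE_REGION_GENES = [
    "MAD", "CBP", "Sanpodo", "orange", "SCF", "en", "inv", "AR1", "AR2",
    "CbpA", "Ubiquitin", "CTD", "Myosin-Va", "IMFamide", "gene15", "gene16",
    "gene17", "gene18", "gene19", "gene20", "gene21", "gene22", "gene23",
    "gene24",
]


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "mimiclocus_run"
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in _STAGES}
    )
    sim: dict[str, Any] = field(default_factory=dict)
    assoc: dict[str, Any] = field(
        default_factory=lambda: {"coding": "dominant", "n_perm": 9999, "alpha": 0.05}
    )
    ld: dict[str, Any] = field(
        default_factory=lambda: {"n_perm": 199, "alpha": 0.05}
    )
    structvar: dict[str, Any] = field(
        default_factory=lambda: {
            "size": 150, "shift": 75, "min_alleles": 3, "min_windows": 2,
            "min_reads": 3, "min_fraction": 0.05,
            "n_carriers": 3, "n_noncarriers": 3,
        }
    )
    molevol: dict[str, Any] = field(
        default_factory=lambda: {
            "use_corrected": True,
            "hka_references": ["dpp", "RpS19", "cdp", "wg"],
        }
    )
    pedigree: dict[str, Any] = field(
        default_factory=lambda: {
            "n_offspring": 50, "crossover_between": [3, 4], "n_recombinants": 2,
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise DataError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(value, dict):
                getattr(cfg, key).update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def sim_config(self) -> SimConfig:
        sim = dict(self.sim)
        sim.setdefault("seed", self.seed)
        if "loci" in sim:
            from mimiclocus.simulate import LocusDef

            sim["loci"] = [LocusDef(**l) if isinstance(l, dict) else l for l in sim["loci"]]
        return SimConfig(**sim)

    def validate(self) -> None:
        sim_cfg = self.sim_config()
        locus_ids = {l.locus_id for l in sim_cfg.loci}
        bad = [r for r in self.molevol["hka_references"] if r not in locus_ids]
        if bad:
            raise DataError(f"HKA reference loci not defined: {bad}")
        for s in self.stages:
            if s not in _STAGES:
                raise DataError(f"unknown stage {s!r}")
        if self.assoc.get("coding") not in assoc_mod.CODINGS:
            raise DataError(f"unknown association coding {self.assoc.get('coding')!r}")


def detect_deletion_carriers(g: GenotypeMatrix) -> list[str]:
    """Individuals carrying at least one copy of any indel allele (the 8-bp
    deletion genotyped as an ordinary biallelic site)."""
    carriers: set[str] = set()
    for j, s in enumerate(g.sites):
        if len(s.ref_allele) == len(s.alt_allele):
            continue
        for i in np.flatnonzero(g.dosage[:, j] >= 1):
            carriers.add(g.individuals[i])
    return sorted(carriers)


def consolidate_duplication_exclusion(
    deletion_carriers: list[str] | None,
    segment_carriers: list[str] | None,
) -> list[str]:
    """Union of duplication carriers from deletion genotyping and from
    read-window segment calls; either source may be absent (skipped)."""
    if deletion_carriers is None and segment_carriers is None:
        logger.warning("no carrier evidence available; exclusion skipped")
        return []
    out = set(deletion_carriers or []) | set(segment_carriers or [])
    return sorted(out)


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run all enabled stages in dependency order and write a report.

    Returns the report dict; also writes ``report.json``, the resolved
    configuration and per-stage TSV artifacts under ``cfg.outdir``.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(_resolved_config(cfg), fh, sort_keys=True)

    report: dict[str, Any] = {"seed": cfg.seed, "skipped": []}
    sim_cfg = cfg.sim_config()

    if not cfg.stages.get("simulate", True):
        raise DataError("the pipeline is simulation-driven; stage 'simulate' is required")
    g, morphs, truth = simulate_population(sim_cfg)
    write_genotypes(g, outdir / "genotypes.vcf")
    _write_phenotypes(morphs, outdir / "phenotypes.tsv")
    gf = filter_by_major_allele(g, 0.97)
    report["population"] = {
        "n_individuals": g.n_individuals,
        "n_sites": g.n_sites,
        "n_sites_after_maf_filter": gf.n_sites,
        "morph_counts": {m: len(morphs.individuals_of(m)) for m in morphs.hierarchy},
    }

    if cfg.stages.get("assoc", True):
        scan_cfg = assoc_mod.ScanConfig(
            coding=cfg.assoc["coding"], n_perm=cfg.assoc["n_perm"], seed=cfg.seed,
        )
        results = assoc_mod.scan(gf, morphs, scan_cfg)
        assoc_mod.results_to_frame(results).to_csv(
            outdir / "association.tsv", sep="\t", index=False, float_format="%.6g"
        )
        top = assoc_mod.top_site_per_morph(results)
        report["assoc"] = {
            morph: {
                "locus": r.site.locus_id,
                "chrom": r.site.chrom,
                "pos": r.site.pos,
                "G": round(r.G, 6),
                "p_perm": r.p_perm,
                "p_bonf": r.p_bonf,
            }
            for morph, r in sorted(top.items())
        }
        fulls = assoc_mod.full_association(gf, morphs)
        report["full_association"] = [
            {
                "morph": f.morph,
                "locus": f.site.locus_id,
                "pos": f.site.pos,
                "allele": f.allele,
                "carriage_above": sorted(f.carriage_above),
            }
            for f in sorted(fulls, key=lambda f: (f.morph, f.site.key))
        ]
    else:
        report["skipped"].append("assoc")

    if cfg.stages.get("ld", True):
        ldm = ld_mod.ld_matrix(
            gf, n_perm=cfg.ld["n_perm"], seed=cfg.seed, alpha=cfg.ld["alpha"]
        )
        ld_mod.write_ld_tables(ldm, outdir, prefix="ld")
        causal = [i for i, s in enumerate(ldm.sites) if s.locus_id == sim_cfg.causal_locus]
        iu = np.triu_indices(len(ldm.sites), k=1)
        within = np.zeros(len(ldm.sites), dtype=bool)
        within[causal] = True
        pair_within = within[iu[0]] & within[iu[1]]
        inter_locus = np.array(
            [ldm.sites[a].locus_id != ldm.sites[b].locus_id for a, b in zip(*iu)]
        )
        r2 = ldm.r2[iu]
        ok = ~np.isnan(r2)
        report["ld"] = {
            "n_defined_pairs": int(ok.sum()),
            "n_significant": int(ldm.significant[iu].sum()),
            "mean_r2_within_causal_locus": _mean(r2[ok & pair_within]),
            "mean_r2_between_loci": _mean(r2[ok & inter_locus]),
        }
    else:
        report["skipped"].append("ld")

    segment_carriers: list[str] | None = None
    if cfg.stages.get("structvar", True):
        sv = cfg.structvar
        deletion_carriers = detect_deletion_carriers(g)
        non_carriers = [i for i in g.individuals if i not in set(deletion_carriers)]
        assay = deletion_carriers[: sv["n_carriers"]] + non_carriers[: sv["n_noncarriers"]]
        read_sets = simulate_reads(truth, sim_cfg, individuals=assay)
        segment_carriers = []
        segments_out = []
        for ind in assay:
            profile = structvar_mod.allele_count_profile(
                read_sets[ind], size=sv["size"], shift=sv["shift"],
                min_reads=sv["min_reads"], min_fraction=sv["min_fraction"],
            )
            structvar_mod.write_profile_tsv(profile, outdir / f"windows_{ind}.tsv")
            segs = structvar_mod.call_duplication_segments(
                profile, min_alleles=sv["min_alleles"], min_windows=sv["min_windows"]
            )
            if segs:
                segment_carriers.append(ind)
            segments_out.extend(
                {"individual": s.individual, "start": s.start, "end": s.end,
                 "max_alleles": s.max_alleles}
                for s in segs
            )
        report["duplication"] = {
            "assayed": assay,
            "segment_carriers": segment_carriers,
            "segments": segments_out,
        }
    else:
        report["skipped"].append("structvar")

    if cfg.stages.get("molevol", True):
        deletion_carriers = detect_deletion_carriers(g)
        excluded = consolidate_duplication_exclusion(deletion_carriers, segment_carriers)
        rng = np.random.default_rng([cfg.seed, 71])
        hap_ids = [f"{ind}/{k}" for ind in g.individuals for k in (0, 1)]
        mk_rows = {}
        hka_loci = {}
        for l in sim_cfg.loci:
            length = 3 * (l.length // 3)
            if length < 30:
                continue
            excess = sim_cfg.causal_nonsyn_excess if l.locus_id == sim_cfg.causal_locus else 1.0
            aln = simulate_outgroup_coding(
                l.locus_id, length, len(hap_ids), sim_cfg.background_theta,
                sim_cfg.outgroup_T, nonsyn_excess=excess, rng=rng,
                haplotype_ids=hap_ids,
            )
            if excluded:
                aln = molevol_mod.exclude_duplication_carriers(aln, excluded)
            counts = molevol_mod.classify_variation(aln)
            row: dict[str, Any] = {
                "Pn": counts.Pn, "Ps": counts.Ps, "Dn": counts.Dn, "Ds": counts.Ds,
            }
            try:
                res = molevol_mod.mk_test(counts, use_corrected=cfg.molevol["use_corrected"])
                row["mk_odds_ratio"] = (
                    round(res.odds_ratio, 6) if np.isfinite(res.odds_ratio) else "inf"
                )
                row["mk_p"] = res.p_value
            except DataError as exc:
                row["mk_p"] = None
                row["flag"] = str(exc)
            mk_rows[l.locus_id] = row
            hka_loci[l.locus_id] = molevol_mod.HKALocus(
                S=counts.Ps, D=counts.Ds, n=len(aln.in_species), sites=counts.sites_syn
            )
        refs = [r for r in cfg.molevol["hka_references"]
                if r in hka_loci and hka_loci[r].S + hka_loci[r].D > 0]
        hka_report: dict[str, Any]
        try:
            hka = molevol_mod.hka_fit(
                molevol_mod.HKAInput(loci=hka_loci), sim_cfg.causal_locus, refs
            )
            hka_report = {
                "focal": sim_cfg.causal_locus,
                "references": refs,
                "X2": round(hka.X2, 6),
                "df": hka.df,
                "p": hka.p_chi2,
                "T_hat": round(hka.T_hat, 6),
                "n_after_exclusion": hka_loci[sim_cfg.causal_locus].n,
            }
        except DataError as exc:
            hka_report = {"error": str(exc)}
        report["molevol"] = {
            "excluded_carriers": excluded,
            "mk": dict(sorted(mk_rows.items())),
            "hka": hka_report,
        }
    else:
        report["skipped"].append("molevol")

    if cfg.stages.get("pedigree", True):
        ped = cfg.pedigree
        brood, btruth = simulate_brood(
            n_offspring=ped["n_offspring"],
            crossover_between=tuple(ped["crossover_between"]),
            n_recombinants=ped["n_recombinants"],
            seed=cfg.seed,
        )
        interval = mapping_mod.crossover_interval(brood)
        report["pedigree"] = {
            "crossover_gaps": [list(gp) for gp in interval.crossover_gaps],
            "left_marker": interval.left_marker,
            "right_marker": interval.right_marker,
            "resolved": interval.resolved,
            "n_recombinant_offspring": len(
                {o for offs in interval.recombinants.values() for o in offs}
            ),
        }
    else:
        report["skipped"].append("pedigree")

    if cfg.stages.get("synteny", True):
        orders = {
            sp: mapping_mod.GeneOrder(
                species=sp, genes=[(gid, "+") for gid in CANDIDATE_REGION_GENES]
            )
            for sp in ("P_dardanus", "H_melpomene", "B_mori")
        }
        syn = {}
        pairs = [("P_dardanus", "H_melpomene"), ("P_dardanus", "B_mori")]
        for a, b in pairs:
            blocks = mapping_mod.collinear_blocks(orders[a], orders[b])
            syn[f"{a}__{b}"] = {
                "n_blocks": blocks.n_blocks,
                "n_breakpoints": blocks.n_breakpoints,
                "shared_genes": blocks.shared_genes,
            }
        report["synteny"] = syn
    else:
        report["skipped"].append("synteny")

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete; report at %s", report_path)
    return report


def _resolved_config(cfg: RunConfig) -> dict[str, Any]:
    out = dataclasses.asdict(cfg)
    sim_cfg = cfg.sim_config()
    out["sim"] = {
        f.name: getattr(sim_cfg, f.name)
        for f in dataclasses.fields(sim_cfg)
    }
    out["sim"]["loci"] = [dataclasses.asdict(l) for l in sim_cfg.loci]
    out["sim"]["causal_allele_freqs"] = [
        round(float(x), 10) for x in sim_cfg.allele_freqs()
    ]
    return out


def _write_phenotypes(morphs, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tmorph\n")
        for ind in sorted(morphs.morph_of):
            fh.write(f"{ind}\t{morphs.morph_of[ind]}\n")


def _mean(x: np.ndarray) -> float | None:
    return round(float(x.mean()), 6) if x.size else None
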