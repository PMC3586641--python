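"""End-to-end analysis pipeline: read -> clone-correct -> diversity ->
distances/Mantel -> PCA/AMOVA/theta -> recombination battery -> PTLPT.

The bundle mirrors the reporting structure of a population survey: a
diversity block per population, a nested-AMOVA block, and a
recombination block (rBarD with P, PrC with P, percent of locus pairs in
LD, PTLPT lengths and P) for the total sample and each population.
Every saved report carries the seed and permutation counts, and a fixed
config + seed reproduces the JSON byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import diversity as dv
from . import partition as pt
from . import recombination as rc
from .genotypes import GenotypeMatrix, allele_frequencies, clone_correct, \
    read_genotype_table
from .parsimony import ptlpt

logger = logging.getLogger("clonepop")


@dataclass
class RunConfig:
    genotype_table: str
    out_dir: str = "results/pipeline"
    dialect: str = "\t"
    clone_scope: str = "dataset"
    n_perm: int = 999
    alpha: float = 0.05
    seed: int = 0
    min_pop_size: int = 5  # populations below this skip the per-pop battery
    ptlpt_n_perm: int = 199  # tree search dominates cost; fewer perms than the rest
    ptlpt_restarts: int = 2
    ptlpt_max_taxa: int = 30  # guard: PTLPT cost grows fast with taxa

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _seeds(seed: int, n: int) -> list[int]:
    """Stage seeds derived deterministically from the master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_pipeline(cfg: RunConfig, g: GenotypeMatrix | None = None) -> dict:
    """Run every stage and write a JSON + TSV bundle under `cfg.out_dir`.

    `g` may be passed directly (e.g. from the simulator); otherwise
    `cfg.genotype_table` is read.  Returns the report dict.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seeds(cfg.seed, 8)
    report: dict = {
        "config": asdict(cfg),
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                logger.info("stage %s", name)
                report["stages"][name] = fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage name
                raise StageError(name, exc) from exc
        return deco

    if g is None:
        @stage("read")
        def _read():
            nonlocal g
            g = read_genotype_table(cfg.genotype_table, cfg.dialect)
            return {"n_samples": g.n_samples, "n_loci": g.n_loci}
    else:
        report["stages"]["read"] = {"n_samples": g.n_samples, "n_loci": g.n_loci}

    cc = clone_correct(g, scope=cfg.clone_scope)
    report["stages"]["clone_correct"] = {
        "scope": cc.scope,
        "n_genotypes": cc.n_samples,
        "n_isolates": int(cc.multiplicity.sum()),
    }

    @stage("diversity")
    def _div():
        rep = dv.diversity_report(g)
        rep.table.to_csv(out / "diversity.tsv", sep="\t", index=False)
        return rep.to_dict()

    multi_pop = len(g.populations) >= 2
    mantel_ok = len(g.populations) >= 4

    @stage("distances")
    def _dist():
        if not multi_pop:
            return {"skipped": "single population"}
        freqs = allele_frequencies(cc, by="population")
        nei = dv.nei_distance(freqs)
        geo = dv.geographic_distance(g)
        alt = dv.altitude_distance(g)
        for name, m in (("nei", nei), ("geographic_km", geo), ("altitude_m", alt)):
            m.as_frame().to_csv(out / f"dist_{name}.tsv", sep="\t")
        block = {"nei": nei.as_frame().to_dict(), "labels": nei.labels}
        if mantel_ok:
            for key, other, sd in (("mantel_geographic", geo, seeds[0]),
                                   ("mantel_altitude", alt, seeds[1])):
                try:
                    res = dv.mantel_test(nei, other, n_perm=cfg.n_perm, seed=sd)
                    block[key] = res.to_dict()
                except ValueError as exc:
                    block[key] = f"skipped: {exc}"
        else:
            block["mantel"] = "skipped: fewer than 4 populations"
        return block

    @stage("structure")
    def _struct():
        if not multi_pop:
            return {"skipped": "single population: AMOVA/theta/PCA undefined"}
        block = {}
        freqs = allele_frequencies(cc, by="population")
        if len(g.populations) >= 3:
            pca = pt.population_pca(freqs)
            block["pca_percent_variance"] = [float(x) for x in pca.percent_variance]
            block["pca_coordinates"] = {
                lab: [float(x) for x in pca.coordinates[i, :2]]
                for i, lab in enumerate(pca.labels)
            }
        try:
            am = pt.amova(cc, n_perm=cfg.n_perm, seed=seeds[2])
            am.table.to_csv(out / "amova.tsv", sep="\t", index=False)
            block["amova"] = am.to_dict()
        except ValueError as exc:
            block["amova"] = f"skipped: {exc}"
        th = pt.theta_weir(cc, n_perm=cfg.n_perm, seed=seeds[3])
        block["theta"] = th.to_dict()
        return block

    @stage("recombination")
    def _recomb():
        block = {}
        targets = [("total", cc)]
        for name, sub in clone_correct(g, scope="population").by_population().items():
            if sub.n_samples >= cfg.min_pop_size:
                targets.append((name, sub))
            else:
                block[name] = {"skipped": f"n = {sub.n_samples} below minimum"}
        for i, (name, sub) in enumerate(targets):
            entry = {"n": sub.n_samples}
            try:
                ia = rc.index_of_association(sub, n_perm=cfg.n_perm,
                                             seed=seeds[4] + i)
                entry["rbard"] = ia.rbard
                entry["rbard_p"] = ia.permutation.p_value
                entry["ia"] = ia.ia
            except ValueError as exc:
                entry["rbard"] = f"skipped: {exc}"
            try:
                ld = rc.pairwise_ld(sub, alpha=cfg.alpha, n_perm=cfg.n_perm,
                                    seed=seeds[5] + i)
                entry["percent_ld"] = ld.percent_significant
            except ValueError as exc:
                entry["percent_ld"] = f"skipped: {exc}"
            comp = rc.compatibility_summary(sub, n_shuffles=cfg.n_perm,
                                            seed=seeds[6] + i)
            entry["prc"] = comp.prc
            entry["prc_p"] = comp.permutation.p_value
            entry["ir"] = comp.ir
            if sub.n_samples <= cfg.ptlpt_max_taxa:
                res = ptlpt(sub, n_perm=cfg.ptlpt_n_perm, seed=seeds[7] + i,
                            restarts=cfg.ptlpt_restarts)
                entry["ptlpt"] = res.to_dict()
            else:
                entry["ptlpt"] = "skipped: sample too large for tree search"
            block[name] = entry
        return block

    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("report written to %s", path)
    return report
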