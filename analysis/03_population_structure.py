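"""Diversity, distance and hierarchical-structure analyses.

Reads the simulated survey table, clone-corrects it, and runs the
population-structure half of the battery: per-population diversity,
Nei / geographic / altitude distance matrices with Mantel tests,
population PCA, nested AMOVA with Phi statistics, and Weir's theta.
"""

import json
from pathlib import Path

from clonepop import (
    allele_frequencies,
    altitude_distance,
    amova,
    clone_correct,
    diversity_report,
    geographic_distance,
    mantel_test,
    nei_distance,
    population_pca,
    read_genotype_table,
    theta_weir,
)

OUT = Path("results")
SEED = 20260920
N_PERM = 999


def main() -> None:
    g = read_genotype_table(OUT / "genotypes.tsv")
    cc = clone_correct(g)
    print(f"{g.n_samples} isolates -> {cc.n_samples} distinct genotypes")

    rep = diversity_report(g)
    rep.table.to_csv(OUT / "diversity.tsv", sep="\t", index=False)
    print("\nper-population diversity (gene diversity / Simpson genotypic):")
    print(rep.table.round(3).to_string(index=False))

    freqs = allele_frequencies(cc)
    nei = nei_distance(freqs)
    geo = geographic_distance(g)
    alt = altitude_distance(g)
    nei.as_frame().round(4).to_csv(OUT / "nei_distance.tsv", sep="\t")
    m_geo = mantel_test(nei, geo, n_perm=N_PERM, seed=SEED)
    m_alt = mantel_test(nei, alt, n_perm=N_PERM, seed=SEED + 1)
    print(f"\nMantel genetic~geographic: r = {m_geo.observed:.3f}, "
          f"P = {m_geo.p_value:.3f}")
    print(f"Mantel genetic~altitude:   r = {m_alt.observed:.3f}, "
          f"P = {m_alt.p_value:.3f}")

    pca = population_pca(freqs)
    print(f"\nPCA: PC1 {pca.percent_variance[0]:.2f}% / "
          f"PC2 {pca.percent_variance[1]:.2f}% of variance")

    am = amova(cc, n_perm=N_PERM, seed=SEED + 2)
    am.table.round(3).to_csv(OUT / "amova.tsv", sep="\t", index=False)
    print("\nAMOVA:")
    print(am.table.round(3).to_string(index=False))
    print({k: round(v, 3) for k, v in am.phi.items()},
          {k: round(v, 3) for k, v in am.phi_p.items()})

    th = theta_weir(cc, n_perm=N_PERM, seed=SEED + 3)
    print(f"\ntheta = {th.theta:.4f} (P = {th.permutation.p_value:.3f})")

    json_out = {
        "mantel_geographic": m_geo.to_dict(),
        "mantel_altitude": m_alt.to_dict(),
        "pca_percent_variance": [float(x) for x in pca.percent_variance],
        "amova": am.to_dict(),
        "theta": th.to_dict(),
    }
    (OUT / "structure.json").write_text(json.dumps(json_out, indent=2))
    print(f"\nwrote {OUT / 'structure.json'}")


if __name__ == "__main__":
    main()
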