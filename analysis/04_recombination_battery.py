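"""Clonality and recombination battery per subpopulation.

Runs, on the clone-corrected total sample and on each clone-corrected
subpopulation with enough genotypes: the rBarD permutation test, the
percent of locus pairs in significant linkage disequilibrium, the
phylogenetic compatibility summary (PrC, IR) and the parsimony
tree-length permutation test.
"""

import json
from pathlib import Path

import pandas as pd

from clonepop import (
    clone_correct,
    compatibility_summary,
    index_of_association,
    pairwise_ld,
    ptlpt,
    read_genotype_table,
)

OUT = Path("results")
SEED = 20260920
N_PERM = 499
PTLPT_PERM = 99
MIN_N = 5


def battery(name: str, sub, seed: int) -> dict:
    entry: dict = {"sample_set": name, "n_genotypes": sub.n_samples}
    try:
        ia = index_of_association(sub, n_perm=N_PERM, seed=seed)
        entry["rbard"] = round(ia.rbard, 3)
        entry["rbard_p"] = round(ia.permutation.p_value, 3)
    except ValueError as exc:
        entry["rbard"] = f"n/a ({exc})"
    try:
        ld = pairwise_ld(sub, n_perm=N_PERM, seed=seed + 1)
        entry["percent_ld"] = round(ld.percent_significant, 1)
    except ValueError:
        entry["percent_ld"] = "n/a"
    comp = compatibility_summary(sub, n_shuffles=N_PERM, seed=seed + 2)
    entry["prc"] = round(comp.prc, 3)
    entry["prc_p"] = round(comp.permutation.p_value, 3)
    entry["ir"] = round(comp.ir, 3) if comp.ir == comp.ir else "n/a"
    if sub.n_samples <= 30:
        res = ptlpt(sub, n_perm=PTLPT_PERM, seed=seed + 3, restarts=2)
        entry["tree_length_observed"] = res.observed_length
        entry["tree_length_null"] = f"{res.null_range[0]}-{res.null_range[1]}"
        entry["ptlpt_p"] = res.p_label
    else:
        entry["ptlpt_p"] = "n/a (too many taxa)"
    return entry


def main() -> None:
    g = read_genotype_table(OUT / "genotypes.tsv")
    rows = [battery("total", clone_correct(g), SEED)]
    per_pop = clone_correct(g, scope="population").by_population()
    for i, (name, sub) in enumerate(per_pop.items()):
        if sub.n_samples >= MIN_N:
            rows.append(battery(name, sub, SEED + 10 * (i + 1)))
        else:
            print(f"{name}: skipped (n = {sub.n_samples} genotypes)")
    tab = pd.DataFrame(rows)
    tab.to_csv(OUT / "recombination.tsv", sep="\t", index=False)
    (OUT / "recombination.json").write_text(json.dumps(rows, indent=2))
    print(tab.to_string(index=False))
    print(f"\nwrote {OUT / 'recombination.tsv'}")


if __name__ == "__main__":
    main()
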