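"""Expression breadth of the family vs a random-transcript background.

Generates the three-design expression data (4 root ages, 14 tissues, 42
cultivars) with the study's planted breadth classes, computes breadth
histograms, contrasts the family against random same-size background draws
(20 bootstrap replicates), extracts the ubiquitous core set, flags monotone
age trends, and clusters the 14 tissue samples into two groups.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from hdzip import expression, simulate
from hdzip.expression import Design


def main(seed: int = 1, outdir: str = "results") -> dict:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {}

    m_ages, t_ages = simulate.gen_expression(
        n_family=117, n_pool=1000, design=Design.AGES4,
        breadth_spec=simulate.DEFAULT_AGES4_BREADTH, seed=seed,
    )
    fam = t_ages["family_ids"]
    expressed = expression.call_expressed(m_ages)
    dist = expression.breadth_distribution(expressed.loc[fam])
    dist.round(1).to_csv(out / "breadth_ages4.tsv", sep="\t")
    pct1 = expression.percent_at_least(expressed.loc[fam], 1)
    print(f"ages design: {int(dist['count'][1:].sum())} of {len(fam)} family "
          f"transcripts expressed in >=1 root age ({pct1:.1f}%)")
    cmp_res = expression.compare_with_random_background(
        fam, t_ages["pool_ids"], m_ages, n_boot=20, seed=seed + 1,
    )
    print(f"random background: {cmp_res.random_at_least_one.mean():.1f} of "
          f"{len(fam)} expressed on average; p = {cmp_res.p_value:.2e} "
          f"({'significant' if cmp_res.significant else 'ns'} at 1e-2)")
    (out / "background_comparison.json").write_text(
        json.dumps(expression.comparison_to_dict(cmp_res), indent=2)
    )
    summary["ages_pct_at_least_one"] = round(pct1, 1)
    summary["background_p"] = cmp_res.p_value

    # core set across the three designs: plant 19 ubiquitous genes
    breadth_19 = {**{0: 40, 1: 30, 2: 28}, 4: 19}
    m_a, t_a = simulate.gen_expression(117, 0, Design.AGES4,
                                       breadth_spec=breadth_19, seed=seed + 2)
    m_t, _ = simulate.gen_expression(117, 0, Design.TISSUES14,
                                     breadth_spec={**{0: 40, 7: 58}, 14: 19},
                                     seed=seed + 3)
    m_c, _ = simulate.gen_expression(117, 0, Design.CULTIVARS42,
                                     breadth_spec={**{0: 40, 21: 58}, 42: 19},
                                     seed=seed + 4)
    core = expression.core_gene_set(
        {d: expression.call_expressed(m) for d, m in
         [("ages4", m_a), ("tissues14", m_t), ("cultivars42", m_c)]}
    )
    print(f"core set expressed in every sample of every design: {len(core)} genes")
    summary["core_set_size"] = len(core)

    trends = expression.age_trend_genes(m_ages.values.loc[fam], min_fold=2.0)
    expression.trends_to_frame(trends).to_csv(out / "age_trends.tsv",
                                              sep="\t", index=False)
    print(f"monotone age trends (fold >= 2): {len(trends)}")

    m_tis, _ = simulate.gen_expression(60, 0, Design.TISSUES14, seed=seed + 5)
    groups = expression.cluster_samples(m_tis, k_groups=2)
    groups.to_csv(out / "tissue_groups.tsv", sep="\t")
    print(f"tissue clustering: {dict(groups.value_counts().sort_index())}")
    (out / "breadth_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    main(args.seed, args.outdir)
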