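"""Statistics of the simulated functional-validation assays.

Knockdown effect sizes via one-way ANOVA with Tukey HSD on the replicate
assay table, percent change versus control, and the chi-square test of the
mosaic-spheroid tip-competition counts against the 50:50 null.  Writes
results/validation_stats.json.
"""

import json
from pathlib import Path

from tipselect import io as tio
from tipselect.valstats import assay_table_comparison, competition_chisq, percent_change

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "results" / "bundle"
OUT = ROOT / "results" / "validation_stats.json"


def main() -> None:
    table = tio.read_assay_table(BUNDLE / "assays.csv")
    results = [r.to_dict() for r in assay_table_comparison(table)]
    means = table.groupby("group")["value"].mean()
    for group in means.index:
        if group != "control":
            red = percent_change(means["control"], means[group])
            print(f"{group}: {red:.1f}% reduction vs control")
            results.append({"name": f"percent_change_{group}", "value": red})

    for cond, counts in tio.read_competition_table(BUNDLE / "competition.csv").items():
        r = competition_chisq(counts)
        frac = 100 * counts.k_silenced_at_tip / counts.n_tips_total
        print(
            f"{cond}: {frac:.1f}% of tips led by the labeled genotype, "
            f"chi2={r.statistic:.3f}, p={r.p_value:.4f}"
        )
        d = r.to_dict()
        d["condition"] = cond
        results.append(d)

    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(results, indent=2) + "\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
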