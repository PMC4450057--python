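"""Characterize the recovered cis-SAGe set against the genome background.

Reads the synthetic run from 03, then: KS comparisons of intergenic
distance / exon counts / flanking intron lengths against the whole-genome
distributions; exon-position histograms around the junction; the exon-2
usage significance test (simulated and exact); coding-impact classes; and
a mock fractionation summary consistent with the coding classes.
"""

import json
from collections import Counter
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from cissage.annotation import genome_background, load_annotation
from cissage.stats import CodingImpact, FractionationRecord, summarize_fractionation

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"
RUN = ROOT / "results" / "filtering" / "synthetic_run"
OUT = ROOT / "results" / "characterization"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ch = json.loads((RUN / "characterization.json").read_text())

    ks = ch["ks_intergenic_distance"]
    print(f"intergenic distance vs genome: KS D = {ks['D']:.4f}, p = {ks['p']:.3e}")
    for side in ("5prime", "3prime"):
        k = ch[f"ks_exon_count_{side}"]
        print(f"exon count ({side}) vs genome: D = {k['D']:.4f}, p = {k['p']:.3e}")
        ki = ch[f"ks_intron_length_{side}"]
        print(f"flanking intron length ({side}): D = {ki['D']:.4f}, p = {ki['p']:.3e}")

    usage = ch["exon2_usage"]
    print(
        f"3' second-exon usage: {usage['observed_k']}/{usage['n_genes']} pairs; "
        f"p_sim = {usage['p_sim']:.2e}, p_exact = {usage['p_exact']:.2e}"
    )
    combos = Counter(ch["junction_combinations"])
    print(f"top junction configurations: {combos.most_common(3)}")

    impacts = Counter(ch["coding_impacts"].values())
    print(f"coding impact of recovered fusions: {dict(impacts)}")

    # mock fractionation panel: NR/out-of-frame fusions nuclear-retained,
    # in-frame ones exported, mirroring the expected biology
    rng = np.random.default_rng(4)
    records, impact_map = [], {}
    for pair, impact in ch["coding_impacts"].items():
        impact_map[pair] = CodingImpact(impact)
        if impact == "in_frame":
            nuc, cyt = rng.uniform(0.3, 0.9), 1.0
        else:
            nuc, cyt = rng.uniform(1.5, 4.0), 1.0
        records.append(FractionationRecord(pair, nuc, cyt))
    summary = summarize_fractionation(records, impact_map)
    print("nuclear enrichment by coding class:")
    for impact, row in summary.crosstab.items():
        if sum(row.values()):
            print(f"  {impact.value}: {row}")

    # background vs recovered-set CDF plot (intergenic distance)
    ann = load_annotation(SIM / "annotation.gtf")
    bg = genome_background(ann)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = np.sort(bg.intergenic_distances) / 1000
    ax.plot(x, np.linspace(0, 1, len(x)), label="genome background")
    ax.axvline(30, color="grey", ls=":", label="30 kb rule")
    ax.set_xscale("log")
    ax.set_xlabel("intergenic distance (kb)")
    ax.set_ylabel("cumulative fraction")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(OUT / "intergenic_distance_cdf.svg")
    print(f"wrote {OUT / 'intergenic_distance_cdf.svg'}")

    (OUT / "characterization.json").write_text(json.dumps(ch, indent=2))


if __name__ == "__main__":
    main()
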