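#!/usr/bin/env python
"""Stage 6: Nei-Li nucleotide diversity per transcript per site population.

Computes per-bp pi from the SNP allele-count tables of each site and tests
whether the two pi distributions differ (two-sample KS).
"""

import json
from pathlib import Path

import numpy as np

from photocoord import diversity as dv, io

DEMO = Path("results/demo")
OUT = Path("results/diversity")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    results = {}
    for site in ("JH", "QG"):
        tables = io.read_snp_tables(DEMO / f"snps_{site}.tsv")
        results[site] = [dv.nei_li_pi(t) for t in tables.values()]
        pis = [r.pi for r in results[site]]
        print(f"{site}: {len(pis)} transcripts, median pi = {np.median(pis):.4f}, "
              f"range {min(pis):.4f}-{max(pis):.4f}")
    dv.write_diversity_table(results, OUT / "pi.tsv")
    ks = dv.compare_site_diversity(results["JH"], results["QG"])
    with open(OUT / "diversity_test.json", "w") as fh:
        json.dump(ks, fh, indent=1)
    verdict = "not significantly different" if ks["p_value"] > 0.05 else "different"
    print(f"KS test JH vs QG: D = {ks['D']:.3f}, p = {ks['p_value']:.4f} "
          f"({verdict})")


if __name__ == "__main__":
    main()
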