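"""Genome QC, HMO-utilization genotyping and AMR/virulence burden.

Simulates per-genome annotations for the three driver species, filters them
by assembly quality, applies the rule-based HMO substrate genotyping and
summarizes AMR/virulence burden and sample-level ESBL carriage.
"""

import pandas as pd

import neostate as ns
from neostate.simulate import (GenomeConfig, simulate_genomes,
                               simulate_sample_esbl_hits)

annotations, truth = simulate_genomes(GenomeConfig(), seed=3)

qc = ns.filter_genomes(annotations)
passed = [r.genome_id for r in qc if r.passed]
print(f"genome QC: {len(passed)} of {len(qc)} genomes pass "
      "(>=90% complete, <=5% contaminated, N50 >= 10 kb, mean contig >= 5 kb, "
      "<= 500 contigs)")

prevalence = ns.genotype_prevalence(annotations.loc[passed])
table = prevalence.pivot(index="substrate", columns="species", values="percentage")
print("\nHMO substrate genotype prevalence (% of genomes per species):")
print(table.round(1).to_string())
print("(B. breve carries the near-complete HMO repertoire, including the "
      "GH95 fucosidase for 2'-FL; E. faecalis has none of it)")

per_genome, medians = ns.amr_virulence_burden(annotations)
print("\nmedian AMR + virulence gene burden per species:")
print(medians.round(1).to_string())

states = pd.Series(["EF"] * 200 + ["BB"] * 100 + ["BL"] * 150,
                   index=[f"s{i}" for i in range(450)])
hits = simulate_sample_esbl_hits(states, seed=3)
flags, per_state = ns.esbl_carriage(hits, states)
print("\nper-state ESBL family carriage rates (fraction of samples):")
print(per_state.round(3).to_string())
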