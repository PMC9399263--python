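"""Correlating taxa across two body sites sampled on the same subjects.

Each subject contributes one sample per ecosystem; sampling fractions and
sequencing efficiencies differ between ecosystems, which defeats methods
built on relative abundances. Bias correction is done per ecosystem, and
features are paired across sites by subject.
"""

import numpy as np

from secom import secom, simulate_two_ecosystems

table, truth = simulate_two_ecosystems(n=60, d=20, dispersion=0.5,
                                       n_cross_pairs=8, rho=0.9, seed=11)
print(f"{table.n_taxa} taxa observed in 2 ecosystems on 60 subjects; "
      "taxa 1-8 correlated across sites")

est = secom(table, method="pearson2", alpha=0.005, seed=2)
ids = est.taxon_ids
cross = [(a, b) for (a, b) in est.support
         if ids[a].split("::")[0] != ids[b].split("::")[0]]
matched = [(a, b) for (a, b) in cross
           if ids[a].split("::")[1] == ids[b].split("::")[1]]
print(f"cross-ecosystem edges found: {len(cross)}, of which matched taxa: {len(matched)}")
vals = [est.matrix[a, b] for a, b in matched]
print("estimates for matched taxa:", np.round(sorted(vals, reverse=True), 2))
print()
print("The matched designed taxa are recovered as strong cross-site edges;")
print("within-site estimates are identical to a per-site analysis by")
print("construction (coherence of the per-ecosystem correction).")
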