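"""miRNA target-site handling: seed-match prediction and AGO CLIP filtering.

Candidate sites (here: predicted by exact 7-mer seed complementarity on a
toy transcript, plus the simulated cohort's candidate table) are retained
only when they overlap an AGO CLIP binding interval by at least one base.
"""

from ceranet import (
    SimConfig,
    collapse_to_pairs,
    filter_by_clip,
    predict_seed_targets,
    simulate_cohort,
)

# seed-match surrogate on a constructed transcript
mirna = {"mir-x": "UGAGGUAGUAGGUUGUAUAGUU"}  # seed (pos 2-8) GAGGUAG
transcript = {"lnc-toy": "AUGC" * 5 + "CUACCUC" + "AUGC" * 5}
cands = predict_seed_targets(mirna, transcript, {"lnc-toy": "lncRNA"})
print("toy prediction:")
print(cands.to_string(index=False))

# CLIP filtering on the simulated candidate table
cohort = simulate_cohort(SimConfig(seed=1))
retained = filter_by_clip(cohort.candidates, cohort.clip_sites)
pairs = collapse_to_pairs(retained)
print(f"\ncandidate sites: {len(cohort.candidates)}")
print(f"CLIP-supported sites: {len(retained)} "
      f"({len(retained) / len(cohort.candidates):.0%}, configured coverage 0.8)")
print(f"unique (miRNA, target) relationships: {len(pairs)}")
# Sites without AGO evidence are discarded; relationships keep a site count.
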