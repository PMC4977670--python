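"""Plant motif instances in synthetic cereal-like promoters and recover them.

Generates 1-kb promoters at GC 0.44, plants the consensus of a 10-bp
MADS-box-like motif at known coordinates, scans both strands with exact
p-values, applies Storey q-values (q <= 0.2) and reports recall against the
planted truth.
"""

import numpy as np

from promscan import (
    PositionMatrix,
    assign_qvalues,
    build_score_distribution,
    estimate_background,
    plant_sites,
    scan_promoters,
    simulate_promoters,
    to_log_odds,
)

probs = np.full((10, 4), 0.02) + np.eye(4)[[1, 2, 0, 3, 3, 0, 0, 3, 3, 1]] * 0.92
motif = PositionMatrix("MADS1", probs, tf_name="SOC1", tf_family="MADS box")
print(f"motif consensus {motif.consensus()}, "
      f"{motif.information_content() / motif.length:.2f} bits/column")

promoters = simulate_promoters(100, 1000, gc=0.44, seed=42)
planted, truth = plant_sites(promoters, [motif], sites_per_gene=1, seed=43)

bg = estimate_background([p.sequence for p in promoters], "cereal")
lo = to_log_odds(motif, bg, pseudo=1e-8)
dist = build_score_distribution(lo, bg)
candidates, null_p = scan_promoters(lo, planted, dist, tf_name="SOC1", tf_family="MADS box")
calls = assign_qvalues(candidates, null_p, q_max=0.2)

truth_set = {(t.gene_id, t.start, t.stop, t.strand) for t in truth.planted_sites}
call_set = {(s.gene_id, s.start, s.stop, s.strand) for s in calls}
recall = len(truth_set & call_set) / len(truth_set)
print(f"planted {len(truth_set)} sites, called {len(call_set)} at q <= 0.2, "
      f"recall {recall:.3f}")
s = calls[0]
print(f"example call: {s.gene_id} [{s.start},{s.stop}] strand {s.strand} "
      f"score {s.score:.2f} bits, p = {s.p_value:.2e}, q = {s.q_value:.3f}")
print("Recall near 1 means the exact-p-value scan recovers essentially every")
print("planted consensus site at its exact coordinates under FDR control.")
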