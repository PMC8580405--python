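"""Graph metrics of a connectivity matrix under proportional thresholding.

Simulates one subject of the default cohort, estimates the alpha-band
imaginary-coherence matrix on the reduced 10-region montage, keeps the
top 30% of edges, and prints node strength (on the weighted matrix) and
the binary-graph measures: clustering coefficient, characteristic path
length (CPL), betweenness centrality.
"""

from hemianet import (
    CohortDesign,
    DEFAULT_EFFECTS,
    betweenness,
    characteristic_path_length,
    clustering,
    epoch_spectra,
    imaginary_coherence,
    node_strength,
    proportional_threshold,
    segment,
    simulate_cohort,
)

design = CohortDesign(n_per_group=2, duration_s=60.0, fs=250.0,
                      effects=DEFAULT_EFFECTS)
cohort = simulate_cohort(design, seed=0, render_eeg=True)
# a baseline (pre-treatment) subject: redundant short-range couplings are
# still strong, so the thresholded graph has triangles and longer paths
rec = cohort.recordings[(1, "pre")]

mat = imaginary_coherence(epoch_spectra(segment(rec)), "Alpha1")
graph = proportional_threshold(mat, p=0.30)
strength = node_strength(mat)
node, global_c = clustering(graph)
glob = characteristic_path_length(graph)
btw = betweenness(graph)

print(f"{graph.n_nodes} regions, {graph.n_edges} edges retained (p = 0.30)")
print(f"global clustering coefficient C = {global_c:.3f}")
print(f"characteristic path length   L = {glob.cpl:.3f}")
print(f"\n{'region':<14} {'strength':>9} {'clustering':>11} {'betweenness':>12}")
for i, label in enumerate(mat.labels):
    print(f"{label:<14} {strength.strength[i]:>9.3f} "
          f"{node.clustering[i]:>11.3f} {btw.betweenness[i]:>12.1f}")
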