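"""Within-site genetic clustering (k-means over PCs, minimum BIC).

Each simulated site pools several family clusters; the BIC curve should
bottom out near the true cluster count, and the discriminant projection
separates the clusters for plotting.
"""

from kinpatch.clustering import discriminant_projection, find_clusters
from kinpatch.simulate import SimulationConfig, simulate_study

table, truth = simulate_study(SimulationConfig(seed=42, n_sites=2))

for site in table.site_labels:
    sub = table.site_table(site)
    true_k = len({truth.cluster_of[i] for i in sub.ids})
    a = find_clusters(sub, max_k=8, seed=5)
    curve = ", ".join(f"k={k}: {b:.1f}" for k, b in sorted(a.bic.items())[:6])
    print(f"{site}: true clusters = {true_k}, selected k = {a.selected_k}")
    print(f"   BIC {curve} ...")
    if a.selected_k >= 2:
        proj = discriminant_projection(sub, a, seed=5)
        print(f"   {proj['n_axes']} discriminant axis/axes "
              f"({'density plot' if proj['n_axes'] == 1 else 'scatter'} data)")
print("\nSelected k tracks the number of family groups pooled into each site.")
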