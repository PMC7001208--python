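"""Call gene deletions from read depth across a 50-sample population.

Simulates Poisson(8) depth tracks with two genes deleted in 10% of samples
and one gene deleted in 40%, calls deletions at mean coverage < 0.05x, and
applies the >= 0.3 population-frequency exclusion.
"""
import admixscan as ax

genes = [ax.GeneInterval(f"g{i}", "chr1", i * 3000, i * 3000 + 2000)
         for i in range(6)]
samples = [f"s{i:02d}" for i in range(50)]
deleted = {}
for i, s in enumerate(samples):
    gone = set()
    if i < 5:
        gone |= {"g1", "g4"}   # 10% frequency
    if i < 20:
        gone.add("g2")         # 40% frequency -> excluded
    deleted[s] = gone

tracks = ax.simulate_depth_tracks(genes, deleted, mean_depth=8, seed=2)
matrix = ax.deletion_matrix(tracks, genes, threshold=0.05)
freq = ax.deletion_frequency(matrix, exclusion_threshold=0.3)
print(freq.to_string(index=False))

# Genes never deleted are flagged "core" (the zero-deletion-frequency
# set); g2 at frequency 0.40 crosses the 0.3 bound and is excluded from
# downstream gene analysis.
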