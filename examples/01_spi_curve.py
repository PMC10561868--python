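"""Decompose the co-occurrence entropy of one cell pattern.

Builds a clustered and a completely random 3-type pattern, computes each
SPI curve, and prints the entropy decomposition.  The clustered pattern
shows positive spatial information at short range (cells of the same type
aggregate), while the random pattern sits at ~0 everywhere: distance
explains none of its co-occurrence heterogeneity.
"""

import numpy as np

from spatent import diversity_baselines, simulate_pattern, spi_from_pattern

for configuration in ("clustered", "random"):
    pattern = simulate_pattern(configuration, n_types=3, cells_per_type=300, seed=1)
    curve = spi_from_pattern(pattern, n_bins=15)
    div = diversity_baselines(pattern)
    print(f"\n{configuration} pattern ({pattern.n_cells} cells, J={pattern.n_types}):")
    print(f"  H(Z)  = {curve.total_entropy:.4f} nats  (global co-occurrence entropy)")
    print(f"  SPI(Z)= {curve.spatial_information:.4f} nats  (entropy explained by distance)")
    print(f"  H^W(Z)= {curve.residual_entropy:.4f} nats  (residual after space)")
    print(f"  Shannon diversity = {div['shannon']:.4f}, Simpson = {div['simpson']:.4f}")
    with np.printoptions(precision=3, suppress=True):
        print(f"  SPI_k at first 5 distance bins: {curve.spi[:5]}")
        print(f"  bin midpoints (microns):        {curve.midpoints[:5]}")
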