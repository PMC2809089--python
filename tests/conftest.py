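import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """Two-sample planted-effect study at desk scale (shared, read-only)."""
    from poolgwas import simulate_two_sample_study

    snp_map, annotation, truth, panels, freqs = simulate_two_sample_study(
        n_snps=20_000, n_genes=200, n_loci=10, effect_size=0.10, seed=29,
        n_chromosomes=10, chrom_length=6_600_000)
    return {"snp_map": snp_map, "annotation": annotation, "truth": truth,
            "panels": panels, "freqs": freqs}


@pytest.fixture(scope="session")
def small_assoc(small_study):
    from poolgwas import associate_panel

    return {k: associate_panel(p) for k, p in small_study["panels"].items()}


@pytest.fixture()
def tiny_map():
    """60 SNPs on two chromosomes with regular spacing."""
    rows = []
    for c, n in (("chr1", 40), ("chr2", 20)):
        pos = np.arange(1, n + 1) * 4_000
        rows.append(pd.DataFrame({
            "snp_id": [f"{c}_s{i}" for i in range(n)], "chrom": c, "pos": pos}))
    return pd.concat(rows, ignore_index=True)


def brute_force_chains(positions, max_gap, min_size):
    """Independent maximal-chain enumeration: plain python loop."""
    chains, current = [], []
    for p in positions:
        if current and p - current[-1] > max_gap:
            chains.append(current)
            current = []
        current.append(p)
    if current:
        chains.append(current)
    return [c for c in chains if len(c) >= min_size]
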