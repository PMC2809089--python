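"""Shared study configuration for the numbered analysis scripts.

The study bundle is regenerated deterministically from STUDY_SEED by every
script (a few seconds at this scale), so no multi-hundred-MB intermediate
panel files need to live on disk; derived tables go to results/.
"""

from pathlib import Path

import poolgwas as pg

RESULTS = Path(__file__).resolve().parent.parent / "results"

STUDY_SEED = 20_260_920
STUDY = dict(
    n_snps=50_000,        # desk-scale stand-in for the 870k-SNP panel
    n_genes=500,
    n_loci=20,            # planted 6-SNP effect blocks shared by both samples
    effect_size=0.10,     # case-control allele-frequency difference
    snps_per_block=6,
    designs={"A": (20, 14), "B": (35, 12)},  # case/control pools per sample
)

PRIMARY_1 = pg.ConvergenceCriteria(3, 25_000)   # converge then cluster
PRIMARY_2 = pg.ConvergenceCriteria(4, 10_000)   # cluster then converge


def load_study():
    snp_map, annotation, truth, panels, freqs = pg.simulate_two_sample_study(
        seed=STUDY_SEED, **STUDY)
    return snp_map, annotation, truth, panels, freqs


def save(df, name, **kwargs):
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=False, **kwargs)
    print(f"  wrote {path.relative_to(RESULTS.parent)}")
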