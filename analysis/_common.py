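"""Shared helpers for the analysis drivers."""

import pathlib

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"
DATA = RESULTS / "data"
SEED = 0


def dataset():
    """The study dataset: loaded from results/data if 01_simulate wrote it,
    regenerated deterministically otherwise."""
    from geothermflora.synthetic import SyntheticConfig, generate, load_dataset

    if (DATA / "config.yaml").exists():
        return load_dataset(DATA)
    return generate(SyntheticConfig(seed=SEED))


def save(df, name, index=False):
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
    print(f"  wrote {path.relative_to(RESULTS.parent)}")
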