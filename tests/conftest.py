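"""Shared fixtures: synthetic bundles and trained models (session-scoped).

The demonstration bundle (n = 2000 labelled regions, planted-motif
positives) and the models trained on it are expensive, so they are built
once per session and shared by the unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pyfaidx
import pytest
from hypothesis import settings

from enhancerselect import cnn, gkm, regions, simulate

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")

DEMO_SEED = 7


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("demo_bundle")
    config = simulate.demo_config(seed=DEMO_SEED)
    bundle = simulate.simulate_bundle(config, out)
    return config, bundle


@pytest.fixture(scope="session")
def demo_genome(demo_bundle):
    _, bundle = demo_bundle
    return pyfaidx.Fasta(str(bundle.genome_path), as_raw=True,
                         sequence_always_upper=True)


@pytest.fixture(scope="session")
def demo_roster(demo_bundle):
    _, bundle = demo_bundle
    return pd.read_csv(bundle.regions_path, sep="\t")


@pytest.fixture(scope="session")
def demo_truth(demo_bundle):
    _, bundle = demo_bundle
    return pd.read_csv(bundle.truth_path, sep="\t")


@pytest.fixture(scope="session")
def demo_records(demo_bundle):
    config, bundle = demo_bundle
    ref = config.comparisons[0]
    return regions.read_differential_table(bundle.differential_paths[ref])


@pytest.fixture(scope="session")
def demo_svm_sets(demo_bundle, demo_genome, demo_records):
    config, bundle = demo_bundle
    examples, log = regions.prepare_svm_examples(
        demo_records, demo_genome,
        regions.read_tss_positions(bundle.tss_path),
        regions.read_bed_intervals(bundle.super_enhancer_path),
        regions.SPLIT_SCHEMES["svm_mouse"],
        comparison=config.comparisons[0])
    sets = {"train": [], "validation": [], "test": []}
    for ex in examples:
        sets[ex.split].append(ex)
    return sets, log


@pytest.fixture(scope="session")
def demo_svm_model(demo_svm_sets):
    """Grid-trained gapped k-mer SVM on the demonstration fixture."""
    sets, _ = demo_svm_sets
    grid = [gkm.GkmConfig(l=l, k=k) for l in (8, 10) for k in (5, 6)]
    return gkm.train(sets["train"], sets["validation"], grid)


@pytest.fixture(scope="session")
def demo_cnn_sets(demo_bundle, demo_genome, demo_records):
    _, bundle = demo_bundle
    bins = regions.bins_from_summits(
        regions.select_differential(demo_records, direction="positive_class")
        + regions.select_differential(demo_records,
                                      direction="negative_class"))
    examples = regions.bin_windows_for_cnn(
        bins, regions.read_bed_intervals(bundle.blacklist_path), demo_genome)
    examples = regions.assign_splits(examples,
                                     regions.SPLIT_SCHEMES["cnn_mouse"])
    sets = {"train": [], "validation": [], "test": []}
    for ex in examples:
        sets[ex.split].append(ex)
    return sets


@pytest.fixture(scope="session")
def demo_cnn_model(demo_cnn_sets):
    """Scaled CNN (restart grid, validation-selected) on the demo fixture."""
    model, results = cnn.train_grid(cnn.scaled_grid(seed=DEMO_SEED),
                                    demo_cnn_sets["train"],
                                    demo_cnn_sets["validation"])
    return model, results


@pytest.fixture(scope="session")
def interp_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("interp_bundle")
    config = simulate.interpretation_config(seed=DEMO_SEED)
    bundle = simulate.simulate_bundle(config, out)
    return config, bundle


@pytest.fixture(scope="session")
def interp_setup(interp_bundle):
    """Two SVMs trained on the interpretation fixture + its positives."""
    config, bundle = interp_bundle
    genome = pyfaidx.Fasta(str(bundle.genome_path), as_raw=True,
                           sequence_always_upper=True)
    tss = regions.read_tss_positions(bundle.tss_path)
    ses = regions.read_bed_intervals(bundle.super_enhancer_path)
    models: dict[str, gkm.TrainedGkmModel] = {}
    prepared: dict[str, list] = {}
    configs = [gkm.GkmConfig(l=10, k=6), gkm.GkmConfig(l=8, k=6)]
    for name, gconf in zip(config.comparisons, configs):
        recs = regions.read_differential_table(bundle.differential_paths[name])
        examples, _ = regions.prepare_svm_examples(
            recs, genome, tss, ses, regions.SPLIT_SCHEMES["svm_mouse"],
            comparison=name)
        sets = {"train": [], "validation": [], "test": []}
        for ex in examples:
            sets[ex.split].append(ex)
        models[name] = gkm.train(sets["train"], sets["validation"], [gconf])
        prepared[name] = examples
    truth = pd.read_csv(bundle.truth_path, sep="\t")
    return config, models, prepared, truth


@pytest.fixture(scope="session")
def small_model():
    """A tiny, quickly trained linear gkm model for unit tests."""
    from enhancerselect.seqs import random_dna

    rng = np.random.default_rng(5)
    motif = "TGACCTTG"

    def make(positive: bool) -> str:
        seq = random_dna(rng, 120)
        if positive:
            i = int(rng.integers(30, 80))
            seq = seq[:i] + motif + seq[i + len(motif):]
        return seq

    train = ([make(i < 60) for i in range(120)],
             np.r_[np.ones(60), np.zeros(60)].astype(int))
    val = ([make(i < 20) for i in range(40)],
           np.r_[np.ones(20), np.zeros(20)].astype(int))
    model = gkm.train(train, val, [gkm.GkmConfig(l=6, k=4)])
    return model, train, val
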