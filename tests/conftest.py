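import numpy as np
import pandas as pd
import pytest

from scissionkit import breakio, simdata


@pytest.fixture(scope="session")
def sim_bundle():
    """One deterministic end-to-end simulation shared across tests."""
    cfg = simdata.SimConfig(seed=1, chrom_length=50_000, n_guides=5, offtargets_per_guide=3)
    genome, truth = simdata.gen_genome(cfg)
    ends = simdata.simulate_break_ends(truth, genome, cfg)
    pileup = breakio.dedup_ends(breakio.filter_mapq(ends))
    ntc_ends = simdata.simulate_nontarget_control(
        genome, cfg, total_molecules=int(pileup["count"].sum())
    )
    ntc = breakio.dedup_ends(ntc_ends)
    return {
        "cfg": cfg,
        "genome": genome,
        "truth": truth,
        "ends": ends,
        "pileup": pileup,
        "ntc": ntc,
    }


@pytest.fixture(scope="session")
def rule_model_reduced():
    """Reduced-flavor model trained on the planted sequence rule."""
    from scissionkit import scissmodel

    instances = simdata.make_rule_instances(1500, seed=3, noise_sd=0.5)
    model, report = scissmodel.train_blunt_model(
        instances, flavor="reduced", seed=3, n_trees=300
    )
    assert report["cv_pearson_r"] > 0.8
    return model


def make_pileup(rows):
    """Helper: pileup frame from (chrom, pos0, strand, count) tuples."""
    return pd.DataFrame(rows, columns=breakio.PILEUP_COLUMNS)


def make_ends(rows):
    """Helper: aligned-end frame from (chrom, pos0, strand, umi) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "pos0", "strand", "umi"])
    df["barcode"] = "AACCGGTT"
    df["mapq"] = 60
    return df[simdata.END_COLUMNS]
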