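import numpy as np
import pandas as pd
import pytest

from ccsatlas.simulate import (
    SimulationConfig,
    simulate_library,
    simulate_records,
    simulate_spectra,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(n_compounds=60, seed=42)


@pytest.fixture(scope="session")
def sim_study(sim_config):
    """A full synthetic study: compounds, ground truth, records, spectra."""
    compounds, truth = simulate_library(sim_config)
    records = simulate_records(truth, sim_config)
    refs, exps = simulate_spectra(compounds, truth, sim_config)
    return {
        "config": sim_config,
        "compounds": compounds,
        "truth": truth,
        "records": records,
        "ref_spectra": refs,
        "exp_spectra": exps,
    }


@pytest.fixture(scope="session")
def clean_study():
    """Noise-, bias- and fault-free study: records equal ground truth."""
    cfg = SimulationConfig(
        n_compounds=40,
        seed=7,
        compound_jitter_pct=0.0,
        lab_bias_sd_pct=0.0,
        noise_sd_pct=0.0,
        replicate_noise_sd_pct=0.0,
        outlier_rate=0.0,
        peak_dropout_rate=0.0,
        intensity_noise_sd=0.0,
        max_contaminant_peaks=0,
    )
    compounds, truth = simulate_library(cfg)
    records = simulate_records(truth, cfg)
    refs, exps = simulate_spectra(compounds, truth, cfg)
    return {
        "config": cfg,
        "compounds": compounds,
        "truth": truth,
        "records": records,
        "ref_spectra": refs,
        "exp_spectra": exps,
    }


@pytest.fixture()
def toy_compounds():
    rows = [
        ("C1", "glucose", "OCC1OC(O)C(O)C(O)C1O"),
        ("C2", "alanine", "CC(N)C(=O)O"),
        ("C3", "benzoic acid", "OC(=O)c1ccccc1"),
    ]
    from rdkit.Chem import MolFromSmiles
    from rdkit.Chem.Descriptors import ExactMolWt

    df = pd.DataFrame(rows, columns=["id", "name", "smiles"])
    df["mass"] = [ExactMolWt(MolFromSmiles(s)) for s in df["smiles"]]
    df["superclass"] = ["Organic oxygen compounds"] * 1 + ["Organic acids and derivatives"] * 2
    df["parsed"] = True
    return df


def make_records(rows):
    """Helper: build a record table from (cid, adduct, ccs, dataset, instrument) tuples."""
    out = []
    for i, (cid, adduct, ccs, dataset, instrument) in enumerate(rows):
        out.append(
            {
                "record_id": f"R{i:04d}",
                "compound_id": cid,
                "adduct": adduct,
                "ccs": ccs,
                "mz_reported": np.nan,
                "dataset_id": dataset,
                "lab_id": f"lab-{dataset}",
                "instrument": instrument,
                "polarity": "+" if adduct.endswith("+") else "-",
            }
        )
    return pd.DataFrame(out)
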