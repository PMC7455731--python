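"""Synthetic multi-lab CCS studies with known ground truth.

The generator emulates the statistical structure of a multi-source CCS
compendium so every pipeline stage is testable offline:

* real small-molecule structures (a bundled curated list of ~100 SMILES
  spanning seven chemical superclasses) -- descriptors and fingerprints
  need valid chemistry;
* synthetic CCS ground truth per superclass following a power law
  CCS = a * (m/z)^b (the same functional form the trend-line outlier
  filter assumes), plus a compound-level jitter;
* multi-dataset experimental records with per-dataset lab bias,
  measurement noise, replicates, and injected outliers whose labels are
  retained as the oracle for recovery tests;
* toy fragment spectra: clean reference libraries plus degraded
  experimental copies (peak dropout, intensity noise, contaminants) and
  decoy candidate databases for ranking benchmarks.

Everything is driven by one seeded :class:`SimulationConfig`; identical
configs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from ccsatlas.adducts import AdductTable, compute_adduct_mz, default_adducts, training_adducts
from ccsatlas.chemio import Spectrum, SpectrumList

__all__ = [
    "DatasetSpec",
    "SimulationConfig",
    "bundled_molecules",
    "simulate_candidate_db",
    "simulate_library",
    "simulate_records",
    "simulate_spectra",
]

#: Per-superclass power-law parameters (a, b) for CCS = a * (m/z)^b,
#: giving CCS ~120-320 A^2 over the bundled mass range.
DEFAULT_POWERLAWS = {
    "Lipids and lipid-like molecules": (9.8, 0.50),
    "Organic acids and derivatives": (8.6, 0.52),
    "Organic oxygen compounds": (8.2, 0.53),
    "Benzenoids": (8.8, 0.51),
    "Phenylpropanoids and polyketides": (8.4, 0.52),
    "Organoheterocyclic compounds": (8.0, 0.53),
    "Nucleosides, nucleotides, and analogues": (7.6, 0.54),
}


@dataclass(frozen=True)
class DatasetSpec:
    dataset_id: str
    lab_id: str
    instrument: str  # DTIM | TWIM | TIMS


DEFAULT_DATASETS = (
    DatasetSpec("DS01", "LabA", "DTIM"),
    DatasetSpec("DS02", "LabB", "DTIM"),
    DatasetSpec("DS03", "LabA", "DTIM"),
    DatasetSpec("DS04", "LabC", "TWIM"),
    DatasetSpec("DS05", "LabD", "TWIM"),
    DatasetSpec("DS06", "LabC", "TIMS"),
)


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic CCS compendium."""

    n_compounds: int = 60
    seed: int = 0
    polarities: tuple = ("+", "-")
    use_all_adducts: bool = False  # False: the 7 training adducts only
    class_powerlaw_params: dict = field(default_factory=lambda: dict(DEFAULT_POWERLAWS))
    compound_jitter_pct: float = 2.0
    datasets: tuple = DEFAULT_DATASETS
    lab_bias_sd_pct: float = 0.5
    coverage: float = 0.8
    max_replicates: int = 2
    noise_sd_pct: float = 0.3
    replicate_noise_sd_pct: float = 0.1
    outlier_rate: float = 0.02
    outlier_magnitude_pct: float = 25.0
    mz_error_ppm_rate: float = 0.0
    mz_error_ppm_magnitude: float = 20.0
    # spectra
    n_peaks_range: tuple = (5, 20)
    peak_dropout_rate: float = 0.2
    intensity_noise_sd: float = 0.1
    max_contaminant_peaks: int = 2
    # candidate database
    decoys_per_compound: int = 15
    decoy_mass_ppm: float = 20.0
    decoy_ccs_spread_pct: float = 15.0

    def __post_init__(self) -> None:
        for rate in (self.coverage, self.outlier_rate, self.peak_dropout_rate, self.mz_error_ppm_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def bundled_molecules() -> pd.DataFrame:
    """The curated structure list shipped with the package."""
    with resources.as_file(resources.files("ccsatlas.data") / "molecules.tsv") as p:
        df = pd.read_csv(p, sep="\t")
    df["id"] = [f"CMP{i:04d}" for i in range(len(df))]
    return df


def _adduct_table(config: SimulationConfig) -> AdductTable:
    return default_adducts() if config.use_all_adducts else training_adducts()


def simulate_library(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw compounds and assign per-adduct ground-truth CCS.

    Returns ``(compounds, truth)``: compounds with id/name/smiles/mass/
    superclass, truth with one row per compound x adduct carrying the ion
    m/z and the true CCS (class power law x compound jitter).
    """
    if config.n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    pool = bundled_molecules()
    if config.n_compounds > len(pool):
        raise ValueError(
            f"bundled structure list holds {len(pool)} molecules; "
            f"requested {config.n_compounds}"
        )
    rng = np.random.default_rng(config.seed)
    idx = rng.choice(len(pool), size=config.n_compounds, replace=False)
    compounds = pool.iloc[np.sort(idx)].reset_index(drop=True).copy()
    from rdkit.Chem.Descriptors import ExactMolWt

    from ccsatlas.chemio import mol_from_structure

    compounds["mass"] = [ExactMolWt(mol_from_structure(s)) for s in compounds["smiles"]]
    compounds["parsed"] = True

    table = _adduct_table(config)
    jitter = rng.normal(0.0, config.compound_jitter_pct / 100.0, size=len(compounds))
    rows = []
    for (_, comp), jit in zip(compounds.iterrows(), jitter):
        a, b = config.class_powerlaw_params[comp["superclass"]]
        for spec in table:
            if spec.polarity not in config.polarities:
                continue
            mz = compute_adduct_mz(comp["mass"], spec)
            if mz <= 0:
                continue
            rows.append(
                {
                    "compound_id": comp["id"],
                    "adduct": spec.name,
                    "polarity": spec.polarity,
                    "mz": mz,
                    "ccs_true": a * mz**b * (1.0 + jit),
                }
            )
    return compounds, pd.DataFrame(rows)


def simulate_records(
    truth: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Generate multi-dataset experimental CCS records from ground truth.

    Per dataset: measured = truth x (1 + lab bias) x (1 + measurement
    noise) [x (1 +/- outlier magnitude)], replicated with small replicate
    noise.  Outlier displacement applies at the measurement level (shared
    by replicates), so injected outliers survive the intra-dataset
    consistency merge and are the trend-line stage's job -- the
    ``is_outlier`` labels are the oracle for recovery tests.
    """
    rng = np.random.default_rng(config.seed + 1)
    biases = rng.normal(0.0, config.lab_bias_sd_pct / 100.0, size=len(config.datasets))
    rows = []
    rid = 0
    for ds, bias in zip(config.datasets, biases):
        for _, t in truth.iterrows():
            if rng.random() > config.coverage:
                continue
            noise = rng.normal(0.0, config.noise_sd_pct / 100.0)
            is_outlier = rng.random() < config.outlier_rate
            displaced = 1.0
            if is_outlier:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                displaced = 1.0 + sign * config.outlier_magnitude_pct / 100.0
            base = t["ccs_true"] * (1.0 + bias) * (1.0 + noise) * displaced
            mz = t["mz"]
            if rng.random() < config.mz_error_ppm_rate:
                mz = mz * (1.0 + config.mz_error_ppm_magnitude * 1e-6)
            n_rep = int(rng.integers(1, config.max_replicates + 1))
            for _ in range(n_rep):
                rep = rng.normal(0.0, config.replicate_noise_sd_pct / 100.0)
                rows.append(
                    {
                        "record_id": f"R{rid:06d}",
                        "compound_id": t["compound_id"],
                        "adduct": t["adduct"],
                        "ccs": base * (1.0 + rep),
                        "mz_reported": mz,
                        "dataset_id": ds.dataset_id,
                        "lab_id": ds.lab_id,
                        "instrument": ds.instrument,
                        "polarity": t["polarity"],
                        "is_outlier": is_outlier,
                    }
                )
                rid += 1
    return pd.DataFrame(rows)


def simulate_spectra(
    compounds: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[SpectrumList, SpectrumList]:
    """Toy fragment spectra: (reference library, degraded experimental copies).

    Reference spectra carry 5-20 peaks below the [M+H]+/[M-H]- precursor;
    experimental copies lose each peak with the dropout rate, get
    multiplicative intensity noise, and gain a few contaminant peaks.
    """
    rng = np.random.default_rng(config.seed + 2)
    prec = {}
    for _, t in truth.iterrows():
        if t["adduct"] in ("[M+H]+", "[M-H]-"):
            prec.setdefault(t["compound_id"], t["mz"])
    refs, exps = SpectrumList(), SpectrumList()
    for _, comp in compounds.iterrows():
        precursor = prec.get(comp["id"], comp["mass"] + 1.00727646688)
        lo, hi = config.n_peaks_range
        k = int(rng.integers(lo, hi + 1))
        mzs = np.sort(rng.uniform(50.0, max(precursor - 1.0, 55.0), size=k))
        intens = rng.uniform(1.0, 100.0, size=k)
        meta = {"NAME": comp["id"], "COMPOUND": comp["name"]}
        refs.append(Spectrum(np.column_stack([mzs, intens]), precursor, dict(meta)))

        keep = rng.random(k) >= config.peak_dropout_rate
        if not keep.any():
            keep[int(rng.integers(k))] = True
        e_mz = mzs[keep]
        e_int = intens[keep] * np.clip(
            1.0 + rng.normal(0.0, config.intensity_noise_sd, size=keep.sum()), 0.05, None
        )
        n_cont = int(rng.integers(0, config.max_contaminant_peaks + 1))
        if n_cont:
            c_mz = rng.uniform(50.0, max(precursor - 1.0, 55.0), size=n_cont)
            c_int = rng.uniform(1.0, 30.0, size=n_cont)
            e_mz = np.concatenate([e_mz, c_mz])
            e_int = np.concatenate([e_int, c_int])
        order = np.argsort(e_mz)
        exps.append(
            Spectrum(np.column_stack([e_mz[order], e_int[order]]), precursor, dict(meta))
        )
    return refs, exps


def simulate_candidate_db(
    compounds: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
    polarity: str = "+",
) -> pd.DataFrame:
    """Decoy-spiked candidate database for annotation benchmarks.

    Each true compound contributes one correct entry (exact mass, true
    CCS for the polarity's primary adduct) plus ``decoys_per_compound``
    decoys with masses within the m/z tolerance window and CCS values
    spread uniformly +/- ``decoy_ccs_spread_pct``% around the truth, so
    the m/z filter alone cannot separate them.
    """
    rng = np.random.default_rng(config.seed + 3)
    primary = "[M+H]+" if polarity == "+" else "[M-H]-"
    tmap = truth[truth["adduct"] == primary].set_index("compound_id")
    rows = []
    for _, comp in compounds.iterrows():
        if comp["id"] not in tmap.index:
            continue
        ccs_true = float(tmap.loc[comp["id"], "ccs_true"])
        rows.append(
            {
                "id": comp["id"],
                "name": comp["name"],
                "mass": comp["mass"],
                "ccs": ccs_true,
                "ccs_source": "unified",
                "is_true": True,
            }
        )
        for d in range(config.decoys_per_compound):
            ppm = rng.uniform(-config.decoy_mass_ppm, config.decoy_mass_ppm)
            spread = rng.uniform(
                -config.decoy_ccs_spread_pct, config.decoy_ccs_spread_pct
            )
            rows.append(
                {
                    "id": f"{comp['id']}-D{d:02d}",
                    "name": f"decoy {d} of {comp['name']}",
                    "mass": comp["mass"] * (1.0 + ppm * 1e-6),
                    "ccs": ccs_true * (1.0 + spread / 100.0),
                    "ccs_source": "predicted-level-4",
                    "is_true": False,
                }
            )
    return pd.DataFrame(rows)
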