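"""Synthetic-data generators with recorded ground truth.

Every generator is deterministic under a fixed seed and produces inputs in
exactly the shapes the analysis modules consume, together with a truth
bundle sufficient to score downstream recovery:

* clade-structured orthogroup sequence sets with planted per-amino-acid
  compositional shifts (i.i.d.-residue multinomial sequences — a documented
  simplification: no phylogenetic autocorrelation within clades);
* binary-character histories evolved on a tree under a two-state chain with
  exact endpoint transition probabilities and recorded per-branch events;
* noisy stopped-flow spectra from a known reaction chain and known species
  spectra; Michaelis-Menten initial-rate tables; FOX standards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancgain import ColumnStates, Phylogeny, TwoStateModel
from .kinetics import (
    KineticModel,
    SpeciesSpectra,
    SpectraMatrix,
    default_species_spectra,
    log_times,
    simulate_chain,
    synthesize_spectra,
)
from .orthocomp import AMINO_ACIDS, OrthogroupTable

logger = logging.getLogger(__name__)

__all__ = [
    "BASELINE_AA_FREQS",
    "PlantedShift",
    "OrthogroupScenario",
    "gen_orthogroup_dataset",
    "gen_character_history",
    "gen_stopped_flow_dataset",
    "gen_mm_dataset",
    "gen_fox_standards",
    "write_orthogroup_files",
]

# Swiss-Prot-style average amino-acid frequencies (normalized below);
# a fixed realistic composition for the null background.
BASELINE_AA_FREQS = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0394, "R": 0.0553,
    "S": 0.0660, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


@dataclass
class PlantedShift:
    """A planted compositional shift: multiply one amino acid's frequency by
    ``fold`` in one clade of one orthogroup (frequencies renormalized)."""

    orthogroup: str
    amino_acid: str
    clade: str
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold-change must be positive")
        if self.amino_acid not in AMINO_ACIDS:
            raise ValueError(f"{self.amino_acid!r} is not a standard amino acid")


@dataclass
class OrthogroupScenario:
    """Study conditions for the compositional-scan generator.

    Defaults: three clades of 50 species each, sequences of mean length 400
    drawn residue-wise from the baseline frequencies, no dropout or
    duplication, no shifts.
    """

    seed: int = 0
    clade_sizes: dict[str, int] = field(default_factory=lambda: {
        "Sauropsida": 50, "Mammalia": 50, "Actinopterygii": 50})
    n_orthogroups: int = 20
    mean_length: int = 400
    length_sd: int = 40
    baseline: dict[str, float] = field(default_factory=lambda: dict(BASELINE_AA_FREQS))
    shifts: list[PlantedShift] = field(default_factory=list)
    dropout: float = 0.0
    duplication: float = 0.0


def _species_names(clade_sizes: dict[str, int]) -> dict[str, str]:
    clade_map = {}
    for clade, n in clade_sizes.items():
        for i in range(n):
            clade_map[f"{clade[:3].lower()}_{i:03d}"] = clade
    return clade_map


def gen_orthogroup_dataset(scenario: OrthogroupScenario) -> tuple[OrthogroupTable, pd.DataFrame]:
    """Generate an OrthogroupTable plus a truth table.

    The truth table records, per orthogroup, its planted shifts and whether
    dropout or duplication touched it (so presence/single-copy filtering can
    be scored). Same scenario (including seed) gives identical output.
    """
    rng = np.random.default_rng(scenario.seed)
    clade_map = _species_names(scenario.clade_sizes)
    base = np.array([scenario.baseline[a] for a in AMINO_ACIDS], dtype=float)
    base = base / base.sum()
    aa = np.array(list(AMINO_ACIDS))

    og_ids = [f"OG{i:04d}" for i in range(scenario.n_orthogroups)]
    shift_lookup: dict[tuple[str, str], list[PlantedShift]] = {}
    for s in scenario.shifts:
        if s.orthogroup not in og_ids:
            raise ValueError(f"planted shift references unknown orthogroup {s.orthogroup!r}")
        shift_lookup.setdefault((s.orthogroup, s.clade), []).append(s)

    orthogroups: dict[str, dict[str, list[str]]] = {}
    truth_rows = []
    for og in og_ids:
        by_species: dict[str, list[str]] = {}
        dropped, duplicated = [], []
        for sp, clade in clade_map.items():
            if scenario.dropout > 0 and rng.random() < scenario.dropout:
                dropped.append(sp)
                continue
            freqs = base.copy()
            for s in shift_lookup.get((og, clade), []):
                freqs[AMINO_ACIDS.index(s.amino_acid)] *= s.fold
            freqs = freqs / freqs.sum()
            n_copies = 2 if (scenario.duplication > 0
                             and rng.random() < scenario.duplication) else 1
            if n_copies == 2:
                duplicated.append(sp)
            seqs = []
            for _ in range(n_copies):
                length = max(30, int(round(rng.normal(scenario.mean_length,
                                                      scenario.length_sd))))
                seqs.append("".join(rng.choice(aa, size=length, p=freqs)))
            by_species[sp] = seqs
        orthogroups[og] = by_species
        shifts = [s for key, lst in shift_lookup.items() if key[0] == og for s in lst]
        truth_rows.append({
            "orthogroup_id": og,
            "n_species": len(by_species),
            "planted": ";".join(f"{s.amino_acid}:{s.clade}:{s.fold}" for s in shifts),
            "dropped_species": len(dropped),
            "duplicated_species": len(duplicated),
        })
    table = OrthogroupTable(orthogroups=orthogroups, clade_map=clade_map)
    return table, pd.DataFrame(truth_rows)


def write_orthogroup_files(table: OrthogroupTable, out_dir) -> dict[str, str]:
    """Write FASTA + membership TSV + clade TSV readable by load_orthogroups."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "sequences.fasta"
    membership = out / "membership.tsv"
    clades = out / "clades.tsv"
    with open(fasta, "w") as fh, open(membership, "w") as mh:
        mh.write("orthogroup_id\tspecies_id\tsequence_id\n")
        for og in sorted(table.orthogroups):
            for sp in sorted(table.orthogroups[og]):
                for i, seq in enumerate(table.orthogroups[og][sp]):
                    sid = f"{og}|{sp}|{i}"
                    fh.write(f">{sid}\n{seq}\n")
                    mh.write(f"{og}\t{sp}\t{sid}\n")
    with open(clades, "w") as ch:
        ch.write("species_id\tclade\n")
        for sp in sorted(table.clade_map):
            ch.write(f"{sp}\t{table.clade_map[sp]}\n")
    return {"fasta": str(fasta), "membership": str(membership), "clades": str(clades)}


def gen_character_history(tree: Phylogeny, rates: tuple[float, float],
                          n_columns: int, seed: int) -> tuple[ColumnStates, pd.DataFrame]:
    """Evolve binary characters along a tree; record true per-branch events.

    The root state is drawn from the stationary distribution; each branch
    samples the child endpoint from the exact two-state transition matrix.
    Events are scored from endpoint pairs (single-change assumption; a
    warning is logged when rate x branch length exceeds 0.5, where multiple
    hits become non-negligible).
    """
    alpha, beta = rates
    model = TwoStateModel(alpha=alpha, beta=beta)
    tree.require_lengths()
    for _, child in tree.branches():
        if max(alpha, beta) * child.length > 0.5:
            logger.warning("branch %s: rate*length > 0.5, multiple hits likely",
                           child.label)
            break
    rng = np.random.default_rng(seed)
    nodes = tree.nodes()
    branches = tree.branches()
    states = {n: np.zeros(n_columns, dtype=np.uint8) for n in nodes}
    pi1 = model.root_prior[1]
    states[tree.root] = (rng.random(n_columns) < pi1).astype(np.uint8)
    event_rows = []
    for parent, child in branches:
        P = model.transition(child.length)
        p1 = np.where(states[parent] == 1, P[1, 1], P[0, 1])
        states[child] = (rng.random(n_columns) < p1).astype(np.uint8)
        gains = int(np.sum((states[parent] == 0) & (states[child] == 1)))
        losses = int(np.sum((states[parent] == 1) & (states[child] == 0)))
        event_rows.append((parent.label, child.label, gains, losses, gains - losses))
    taxa = sorted(tree.leaves)
    mat = np.stack([states[tree.leaves[t]] for t in taxa], axis=1)
    columns = ColumnStates(taxa=taxa, states=mat,
                           mask=np.zeros_like(mat, dtype=bool))
    truth = pd.DataFrame(event_rows, columns=["parent_label", "child_label",
                                              "gains", "losses", "net"])
    # keep internal-node states available for scoring
    truth.attrs["node_states"] = {n.label: states[n].copy() for n in nodes}
    return columns, truth


def gen_stopped_flow_dataset(model: KineticModel, seed: int,
                             spectra: SpeciesSpectra | None = None,
                             times: np.ndarray | None = None,
                             noise_sigma: float = 0.002) -> tuple[SpectraMatrix, dict]:
    """Simulate chain -> Beer-Lambert spectra -> additive Gaussian noise.

    Defaults emulate the single-turnover design: 25 uM initial urate,
    log-spaced acquisition times from 1 ms, noise sigma 0.002 AU.
    """
    if noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    if spectra is None:
        spectra = default_species_spectra()
    if times is None:
        times = log_times()
    rng = np.random.default_rng(seed)
    profiles = simulate_chain(model, times)
    matrix = synthesize_spectra(profiles, times, spectra, noise_sigma=noise_sigma,
                                rng=rng)
    truth = {"model": model, "profiles": profiles, "spectra": spectra,
             "noise_sigma": noise_sigma}
    return matrix, truth


def gen_mm_dataset(km: float, kcat: float, enzyme_conc: float = 0.5,
                   substrate: np.ndarray | None = None, noise_cv: float = 0.02,
                   replicates: int = 3, seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Initial-rate table v = kcat E S / (K_M + S) with multiplicative noise.

    Default substrate grid spans 2-140 uM; noise is Gaussian with coefficient
    of variation ``noise_cv`` per replicate.
    """
    if km <= 0 or kcat <= 0:
        raise ValueError("K_M and k_cat must be positive")
    if substrate is None:
        substrate = np.array([2.0, 5.0, 10.0, 20.0, 40.0, 80.0, 140.0])
    substrate = np.asarray(substrate, dtype=float)
    if substrate.size == 0:
        raise ValueError("empty substrate grid")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        v_true = kcat * enzyme_conc * substrate / (km + substrate)
        noise = rng.normal(0.0, noise_cv, size=substrate.size) if noise_cv > 0 else 0.0
        v = np.clip(v_true * (1.0 + noise), 0.0, None)
        for s, rate in zip(substrate, v):
            rows.append({"substrate_uM": s, "rate_uM_per_s": rate, "replicate": rep})
    truth = {"km": km, "kcat": kcat, "enzyme_conc": enzyme_conc,
             "vmax": kcat * enzyme_conc}
    return pd.DataFrame(rows), truth


def gen_fox_standards(slope: float = 0.005, intercept: float = 0.04,
                      noise_sigma: float = 0.0, seed: int = 0,
                      concentrations: np.ndarray | None = None) -> tuple[pd.DataFrame, dict]:
    """FOX-assay standards (A595 vs [H2O2]) at 10, 25, 50, 100 uM by default."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    if noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    if concentrations is None:
        concentrations = np.array([10.0, 25.0, 50.0, 100.0])
    c = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    a = slope * c + intercept
    if noise_sigma > 0:
        a = a + rng.normal(0.0, noise_sigma, size=c.size)
    standards = pd.DataFrame({"h2o2_uM": c, "a595": a})
    return standards, {"slope": slope, "intercept": intercept}
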