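"""Synthetic paired molecule/spectrum corpora for end-to-end testing.

Real spectral libraries are proprietary, so this module builds corpora
with the same *structure*: formula strata of constitutional isomers
(so candidate ranking is well-posed), several collision energies per
molecule, and a deterministic molecule -> spectrum map.

Molecules are saturated acyclic C/N/O structures enumerated as random
valence-respecting trees over a heavy-atom multiset, deduplicated by
canonical SMILES — every member of a formula family is a real, distinct
constitutional isomer. Spectra come from a chemically naive but strictly
structure-dependent fragmentation rule: every acyclic bond cleavage
yields two fragments whose masses (plus the charge carrier) become
peaks, with intensity decaying exponentially in fragment mass; the decay
steepens with collision energy, so higher energies shift intensity
toward smaller fragments, as on a real instrument. Optional
multiplicative log-normal noise models detector variability.

Because the rule is a deterministic function of structure, the map is
learnable by construction; distinct isomers get distinct spectra.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from . import chemdata
from .chemdata import (EnergyNormalizer, InstrumentSetting, MoleculeRecord,
                       PairedCorpus, Spectrum)

_VALENCE = {"C": 4, "N": 3, "O": 2}
_H_MASS = 1.00794
PROTON_MASS = 1.00728

#: m/z offset of the ionized molecule for each supported precursor type
ADDUCT_OFFSETS = {
    "[M+H]+": PROTON_MASS,
    "[M+H-H2O]+": PROTON_MASS - 18.01056,
    "[M+H-2H2O]+": PROTON_MASS - 36.02113,
    "[M+H-NH3]+": PROTON_MASS - 17.02655,
    "[M+Na]+": 22.98922,
}

#: default formula families: 30 strata of saturated acyclic C/N/O isomers,
#: 10 isomers each — mirrors a training corpus of ~300 molecules with
#: multi-member candidate strata at every formula.
DEFAULT_FAMILIES: dict[str, int] = {
    f: 10 for f in (
        "C5H12O", "C6H14O", "C7H16O", "C8H18O",
        "C5H12O2", "C6H14O2", "C7H16O2", "C8H18O2",
        "C5H12O3", "C6H14O3", "C7H16O3",
        "C5H13N", "C6H15N", "C7H17N", "C8H19N",
        "C5H13NO", "C6H15NO", "C7H17NO", "C8H19NO",
        "C5H14N2", "C6H16N2", "C7H18N2",
        "C4H11NO", "C4H10O2", "C4H10O3", "C4H12N2",
        "C6H15NO2", "C5H13NO2", "C6H16N2O", "C8H18O3",
    )
}


@dataclass
class SyntheticConfig:
    """Study conditions for corpus generation."""

    families: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_FAMILIES))
    energies: tuple[float, ...] = (10.0, 20.0, 40.0)   # eV grid
    sigma: float = 0.0            # log-normal noise scale on peak intensities
    seed: int = 0
    precursor_types: tuple[str, ...] = chemdata.DEFAULT_PRECURSOR_TYPES
    n_bins: int = chemdata.DEFAULT_N_BINS
    fp_bits: int = chemdata.DEFAULT_FP_BITS
    fp_radius: int = chemdata.DEFAULT_FP_RADIUS
    spectra_cap: int = chemdata.DEFAULT_SPECTRA_CAP
    decay_base: float = 1.0       # fragment-mass decay at zero collision energy
    decay_energy: float = 2.0     # additional decay per unit normalized energy

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("noise level sigma must be >= 0")
        for f, c in self.families.items():
            if c < 1:
                raise ValueError(f"isomer count for {f} must be >= 1")


def _parse_family_formula(formula: str) -> dict[str, int]:
    """Parse a C/H/N/O formula and check it is saturated-acyclic-consistent."""
    counts = {"C": 0, "H": 0, "N": 0, "O": 0}
    for elem, num in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if not elem:
            continue
        if elem not in counts:
            raise ValueError(f"family {formula!r}: element {elem} unsupported (C/H/N/O only)")
        counts[elem] += int(num) if num else 1
    n_heavy = counts["C"] + counts["N"] + counts["O"]
    if n_heavy < 1:
        raise ValueError(f"family {formula!r} has no heavy atoms")
    expect_h = 2 * counts["C"] + counts["N"] + 2
    if counts["H"] != expect_h:
        raise ValueError(
            f"family {formula!r} is not a saturated acyclic C/N/O formula "
            f"(expected H{expect_h})")
    return counts


def _random_valence_tree(atoms: list[str], rng: np.random.Generator) -> Chem.Mol | None:
    """Grow a random tree over the atom multiset, respecting valences."""
    order = rng.permutation(len(atoms))
    mol = Chem.RWMol()
    for i in order:
        mol.AddAtom(Chem.Atom(atoms[i]))
    degree = [0] * len(atoms)
    cap = [_VALENCE[atoms[i]] for i in order]
    for j in range(1, len(atoms)):
        open_slots = [k for k in range(j) if degree[k] < cap[k]]
        if not open_slots:
            return None
        parent = open_slots[rng.integers(len(open_slots))]
        mol.AddBond(int(parent), int(j), Chem.BondType.SINGLE)
        degree[parent] += 1
        degree[j] += 1
    m = mol.GetMol()
    if Chem.SanitizeMol(m, catchErrors=True) != Chem.SanitizeFlags.SANITIZE_NONE:
        return None
    return m


def enumerate_isomers(formula: str, count: int, seed: int = 0,
                      max_attempts_per_isomer: int = 2000) -> list[str]:
    """Enumerate ``count`` distinct constitutional isomers of ``formula``.

    Seeded random tree sampling with canonical-SMILES deduplication;
    raises when the family cannot supply the requested number of isomers.
    """
    counts = _parse_family_formula(formula)
    atoms = ["C"] * counts["C"] + ["N"] * counts["N"] + ["O"] * counts["O"]
    rng = np.random.default_rng(seed)
    found: list[str] = []
    seen: set[str] = set()
    attempts = 0
    budget = max_attempts_per_isomer * count
    while len(found) < count and attempts < budget:
        attempts += 1
        mol = _random_valence_tree(atoms, rng)
        if mol is None:
            continue
        smi = Chem.MolToSmiles(mol)
        if smi not in seen:
            seen.add(smi)
            found.append(smi)
    if len(found) < count:
        raise ValueError(
            f"family {formula}: only {len(found)} distinct isomers found "
            f"(requested {count})")
    return found


def generate_molecules(cfg: SyntheticConfig) -> list[MoleculeRecord]:
    """Enumerate and featurize all molecules of the configured families."""
    records = []
    for fam_idx, (formula, count) in enumerate(sorted(cfg.families.items())):
        smiles = enumerate_isomers(formula, count, seed=cfg.seed * 10007 + fam_idx)
        for i, smi in enumerate(smiles):
            rec = chemdata.parse_molecule(smi, mol_id=f"{formula}-{i:02d}",
                                          fp_bits=cfg.fp_bits, fp_radius=cfg.fp_radius)
            records.append(rec)
    return records


# ----------------------------------------------------------------------
# fragmentation
# ----------------------------------------------------------------------

def _fragment_masses(smiles: str) -> tuple[float, list[float]]:
    """Parent mass and the masses of all single-bond-cleavage fragments.

    Each acyclic bond split yields two fragments; a fragment's mass is
    the sum of its heavy-atom masses plus the hydrogens those atoms
    carry in the parent molecule. Ring bonds (whose removal leaves the
    graph connected) are skipped.
    """
    mol = Chem.MolFromSmiles(smiles)
    n = mol.GetNumAtoms()
    masses = np.array([a.GetMass() + a.GetTotalNumHs() * _H_MASS for a in mol.GetAtoms()])
    adj = [[] for _ in range(n)]
    bonds = []
    for b in mol.GetBonds():
        u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        adj[u].append(v)
        adj[v].append(u)
        bonds.append((u, v))
    parent_mass = float(masses.sum())
    frags: list[float] = []
    for u, v in bonds:
        # component of u with edge (u,v) removed
        comp = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            for w in adj[x]:
                if (x, w) in ((u, v), (v, u)):
                    continue
                if w not in comp:
                    comp.add(w)
                    stack.append(w)
        if v in comp:
            continue   # ring bond: cleavage does not split the molecule
        m_u = float(masses[list(comp)].sum())
        frags.extend([m_u, parent_mass - m_u])
    return parent_mass, frags


def simulate_spectrum(record: MoleculeRecord, setting: InstrumentSetting,
                      cfg: SyntheticConfig,
                      rng: np.random.Generator | None = None,
                      precursor_type: str | None = None) -> Spectrum:
    """Deterministic fragmentation spectrum for one molecule and setting.

    Peaks sit at fragment mass + charge-carrier mass; intensity is
    exp(-(decay_base + decay_energy * CE) * mass / 100), so higher
    collision energy monotonically shifts the intensity-weighted mean
    mass downward. With ``cfg.sigma > 0`` each peak intensity is
    multiplied by log-normal noise drawn from ``rng``.
    """
    if precursor_type is None:
        precursor_type = cfg.precursor_types[int(np.argmax(setting.precursor_onehot))]
    offset = ADDUCT_OFFSETS[precursor_type]
    parent_mass, frags = _fragment_masses(record.smiles)
    lam = (cfg.decay_base + cfg.decay_energy * setting.collision_energy) / 100.0
    peaks = []
    for m in frags + [parent_mass]:
        inten = float(np.exp(-lam * m))
        if cfg.sigma > 0:
            if rng is None:
                raise ValueError("rng required when sigma > 0")
            inten *= float(np.exp(cfg.sigma * rng.standard_normal()))
        peaks.append((m + PROTON_MASS, inten))
    return chemdata.bin_spectrum(peaks, precursor_mz=parent_mass + offset,
                                 setting=setting, n_bins=cfg.n_bins,
                                 molecule_id=record.id)


def generate_corpus(cfg: SyntheticConfig, split_seed: int | None = None) -> PairedCorpus:
    """Full paired corpus: molecules x collision-energy grid, capped and split."""
    records = generate_molecules(cfg)
    normalizer = EnergyNormalizer.fit(list(cfg.energies))
    rng = np.random.default_rng(cfg.seed + 777)
    pairs = []
    for rec in records:
        for e in cfg.energies:
            setting = InstrumentSetting.make(cfg.precursor_types[0], normalizer(e),
                                             vocabulary=cfg.precursor_types)
            pairs.append((rec.id, simulate_spectrum(rec, setting, cfg, rng=rng)))
    corpus = PairedCorpus(molecules={r.id: r for r in records}, pairs=pairs,
                          n_bins=cfg.n_bins)
    corpus = chemdata.cap_spectra_per_molecule(corpus, cap=cfg.spectra_cap,
                                               seed=cfg.seed + 1)
    corpus = chemdata.split_random(corpus, seed=cfg.seed if split_seed is None else split_seed)
    corpus.validate()
    return corpus


# ----------------------------------------------------------------------
# motif corpus for topic-model tests
# ----------------------------------------------------------------------

def generate_motif_spectra(n_motifs: int = 3, spectra_per_motif: int = 50,
                           bins_per_motif: int = 8, n_bins: int = 200,
                           seed: int = 0) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Spectra drawn from disjoint peak motifs, for topic-recovery checks.

    Each motif is a disjoint set of bins; every spectrum activates a
    random subset (at least two) of its motif's bins with random
    intensities. Returns (spectra matrix, motif assignment per spectrum,
    list of motif bin arrays).
    """
    rng = np.random.default_rng(seed)
    if n_motifs * bins_per_motif > n_bins:
        raise ValueError("motifs do not fit in the requested number of bins")
    all_bins = rng.choice(n_bins, size=n_motifs * bins_per_motif, replace=False)
    motif_bins = [np.sort(all_bins[i * bins_per_motif:(i + 1) * bins_per_motif])
                  for i in range(n_motifs)]
    X = np.zeros((n_motifs * spectra_per_motif, n_bins))
    labels = np.zeros(n_motifs * spectra_per_motif, dtype=int)
    row = 0
    for m in range(n_motifs):
        for _ in range(spectra_per_motif):
            active = motif_bins[m][rng.random(bins_per_motif) < 0.8]
            if len(active) < 2:
                active = rng.choice(motif_bins[m], size=2, replace=False)
            X[row, active] = rng.uniform(0.5, 1.0, size=len(active))
            X[row] /= np.linalg.norm(X[row])
            labels[row] = m
            row += 1
    return X, labels, motif_bins
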