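"""Molecule/spectrum corpus handling: parsing, featurization, binning, splits.

Molecules are parsed with RDKit into records carrying a canonical SMILES,
a Hill-notation formula, an ECFP bit fingerprint, MACCS keys (used only
for similarity and clustering), and a featurized molecular graph whose
nodes are heavy atoms and whose edges are bonds with a categorical bond
type. Spectra are fixed-length vectors of summed peak intensities over
1-Da m/z bins, L2-normalized so that the dot product of two spectra is
their cosine similarity.

Splits are always assigned at the molecule level: every spectrum of a
molecule shares its split, so no structure leaks between train and test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, MACCSkeys, rdMolDescriptors

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: heavy-atom vocabulary for graph node one-hots
ATOM_TYPES: tuple[str, ...] = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")
#: closed bond-type vocabulary for edge categories
BOND_TYPES: tuple[str, ...] = ("SINGLE", "DOUBLE", "TRIPLE", "AROMATIC")

DEFAULT_N_BINS = 1000
DEFAULT_BIN_WIDTH = 1.0  # Da
DEFAULT_FP_BITS = 4096
DEFAULT_FP_RADIUS = 2
DEFAULT_SPECTRA_CAP = 5

#: default precursor-type vocabulary: primary protonated mode only
DEFAULT_PRECURSOR_TYPES: tuple[str, ...] = ("[M+H]+",)
#: extended positive-mode vocabulary
POSITIVE_MODE_PRECURSOR_TYPES: tuple[str, ...] = (
    "[M+H]+", "[M+H-H2O]+", "[M+H-2H2O]+", "[M+H-NH3]+", "[M+Na]+",
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class MolecularGraph:
    """Featurized molecular graph: nodes are heavy atoms, edges are bonds.

    ``edges`` is symmetric: (u, v) is present iff (v, u) is, so directed
    message passing over it covers both bond directions.
    """

    atom_types: np.ndarray      # (n_nodes,) int index into ATOM_TYPES
    atom_masses: np.ndarray     # (n_nodes,) float, atomic mass in Da
    edge_index: np.ndarray      # (n_edges, 2) int, symmetric directed pairs
    edge_types: np.ndarray      # (n_edges,) int index into BOND_TYPES

    @property
    def n_nodes(self) -> int:
        return len(self.atom_types)

    @property
    def n_edges(self) -> int:
        return len(self.edge_index)

    def node_features(self) -> np.ndarray:
        """One-hot atom type concatenated with scaled atom mass, (n, |A|+1)."""
        feats = np.zeros((self.n_nodes, len(ATOM_TYPES) + 1))
        feats[np.arange(self.n_nodes), self.atom_types] = 1.0
        feats[:, -1] = self.atom_masses / 100.0  # keep mass O(1)
        return feats


@dataclass(frozen=True)
class InstrumentSetting:
    """Instrument metadata: one-hot precursor type + normalized collision energy."""

    precursor_onehot: np.ndarray
    collision_energy: float

    def __post_init__(self):
        s = float(self.precursor_onehot.sum())
        if not np.isclose(s, 1.0):
            raise ValueError(f"precursor one-hot must sum to 1, got {s}")
        if not (0.0 <= self.collision_energy <= 1.0):
            raise ValueError(
                f"collision energy must be normalized to [0,1], got {self.collision_energy}"
            )

    @classmethod
    def make(cls, precursor_type: str, collision_energy: float,
             vocabulary: tuple[str, ...] = DEFAULT_PRECURSOR_TYPES) -> "InstrumentSetting":
        if precursor_type not in vocabulary:
            raise ValueError(f"precursor type {precursor_type!r} not in vocabulary {vocabulary}")
        onehot = np.zeros(len(vocabulary))
        onehot[vocabulary.index(precursor_type)] = 1.0
        return cls(onehot, float(collision_energy))

    def features(self) -> np.ndarray:
        return np.concatenate([self.precursor_onehot, [self.collision_energy]])


@dataclass(frozen=True)
class MoleculeRecord:
    """A parsed molecule with all featurizations downstream modules need."""

    id: str
    smiles: str
    formula: str
    fingerprint: np.ndarray   # ECFP bits, uint8
    graph: MolecularGraph
    maccs: np.ndarray         # 167 MACCS keys, uint8


@dataclass(frozen=True)
class Spectrum:
    """A binned, normalized intensity vector with instrument metadata."""

    intensities: np.ndarray
    precursor_mz: float
    setting: InstrumentSetting
    molecule_id: str | None = None

    def __post_init__(self):
        v = self.intensities
        if v.ndim != 1:
            raise ValueError("intensities must be a 1-D vector")
        if (v < 0).any():
            raise ValueError("intensities must be non-negative")
        if not (v > 0).any():
            raise ValueError("spectrum must have at least one positive bin")


@dataclass
class PairedCorpus:
    """Paired (molecule, spectrum) records with molecule-level split labels."""

    molecules: dict[str, MoleculeRecord]
    pairs: list[tuple[str, Spectrum]]          # (molecule_id, spectrum)
    splits: dict[str, str] = field(default_factory=dict)   # molecule_id -> train/val/test
    clusters: dict[str, int] = field(default_factory=dict)
    n_bins: int = DEFAULT_N_BINS

    def molecule_ids(self) -> list[str]:
        return list(self.molecules)

    def pairs_in_split(self, split: str) -> list[tuple[str, Spectrum]]:
        return [(mid, s) for mid, s in self.pairs if self.splits.get(mid) == split]

    def molecules_in_split(self, split: str) -> list[MoleculeRecord]:
        return [m for mid, m in self.molecules.items() if self.splits.get(mid) == split]

    def validate(self) -> None:
        for mid, _ in self.pairs:
            if mid not in self.molecules:
                raise ValueError(f"spectrum references unknown molecule {mid!r}")
        for mid, s in self.splits.items():
            if s not in ("train", "val", "test"):
                raise ValueError(f"bad split label {s!r} for molecule {mid!r}")


# ----------------------------------------------------------------------
# molecule parsing / featurization
# ----------------------------------------------------------------------

def parse_molecule(smiles: str, mol_id: str | None = None,
                   fp_bits: int = DEFAULT_FP_BITS,
                   fp_radius: int = DEFAULT_FP_RADIUS) -> MoleculeRecord:
    """Parse a SMILES string into a fully featurized :class:`MoleculeRecord`.

    Raises :class:`SmilesParseError` for unparsable input or molecules
    with no heavy atoms, and ``ValueError`` for atoms outside the
    configured element vocabulary.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES {smiles!r}")
    if mol.GetNumHeavyAtoms() == 0:
        raise SmilesParseError(f"molecule {smiles!r} has no heavy atoms")

    canonical = Chem.MolToSmiles(mol)
    formula = rdMolDescriptors.CalcMolFormula(mol)
    # strip charge suffix like "+" so the formula is a plain Hill string
    formula = formula.rstrip("+-")

    fp = AllChem.GetMorganFingerprintAsBitVect(mol, fp_radius, nBits=fp_bits)
    fingerprint = np.zeros(fp_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        fingerprint[bit] = 1

    maccs_fp = MACCSkeys.GenMACCSKeys(mol)
    maccs = np.zeros(maccs_fp.GetNumBits(), dtype=np.uint8)
    for bit in maccs_fp.GetOnBits():
        maccs[bit] = 1

    atom_types = []
    atom_masses = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in ATOM_TYPES:
            raise ValueError(f"atom type {sym!r} in {smiles!r} outside vocabulary {ATOM_TYPES}")
        atom_types.append(ATOM_TYPES.index(sym))
        atom_masses.append(atom.GetMass())

    src, dst, etypes = [], [], []
    for bond in mol.GetBonds():
        bname = bond.GetBondType().name
        if bname not in BOND_TYPES:
            raise ValueError(f"bond type {bname!r} outside vocabulary {BOND_TYPES}")
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        src += [u, v]
        dst += [v, u]
        etypes += [BOND_TYPES.index(bname)] * 2

    graph = MolecularGraph(
        atom_types=np.asarray(atom_types, dtype=np.intp),
        atom_masses=np.asarray(atom_masses),
        edge_index=np.asarray(list(zip(src, dst)), dtype=np.intp).reshape(-1, 2),
        edge_types=np.asarray(etypes, dtype=np.intp),
    )
    return MoleculeRecord(
        id=mol_id if mol_id is not None else canonical,
        smiles=canonical,
        formula=formula,
        fingerprint=fingerprint,
        graph=graph,
        maccs=maccs,
    )


# ----------------------------------------------------------------------
# spectrum binning
# ----------------------------------------------------------------------

def bin_spectrum(peaks: list[tuple[float, float]],
                 precursor_mz: float,
                 setting: InstrumentSetting,
                 n_bins: int = DEFAULT_N_BINS,
                 molecule_id: str | None = None,
                 sqrt_transform: bool = False) -> Spectrum:
    """Bin a peak list into ``n_bins`` 1-Da bins and L2-normalize.

    Bin convention is half-open [m, m+1): a peak at m/z falls into bin
    ``floor(mz)``. Peaks at or above ``n_bins`` Da are dropped (their
    count is logged). Raises ``ValueError`` when no in-range peak with
    positive intensity remains, since an all-zero spectrum is invalid.
    """
    if not peaks:
        raise ValueError("empty peak list")
    vec = np.zeros(n_bins)
    dropped = 0
    for mz, inten in peaks:
        if mz <= 0:
            raise ValueError(f"non-positive m/z {mz}")
        if inten < 0:
            raise ValueError(f"negative intensity {inten}")
        b = int(np.floor(mz))
        if b >= n_bins:
            dropped += 1
            continue
        vec[b] += inten
    if dropped:
        logger.info("bin_spectrum: dropped %d peak(s) at or above %d Da", dropped, n_bins)
    if not (vec > 0).any():
        raise ValueError("all peaks out of range or zero: cannot build an all-zero spectrum")
    if sqrt_transform:
        vec = np.sqrt(vec)
    vec = vec / np.linalg.norm(vec)
    return Spectrum(intensities=vec, precursor_mz=float(precursor_mz),
                    setting=setting, molecule_id=molecule_id)


# ----------------------------------------------------------------------
# corpus operations
# ----------------------------------------------------------------------

def cap_spectra_per_molecule(corpus: PairedCorpus, cap: int = DEFAULT_SPECTRA_CAP,
                             seed: int = 0) -> PairedCorpus:
    """Down-sample molecules with more than ``cap`` spectra to exactly ``cap``.

    Sampling is with replacement (duplicates are kept), seeded for
    determinism; molecules at or below the cap keep all spectra as-is.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rng = np.random.default_rng(seed)
    by_mol: dict[str, list[Spectrum]] = {}
    for mid, s in corpus.pairs:
        by_mol.setdefault(mid, []).append(s)
    new_pairs: list[tuple[str, Spectrum]] = []
    for mid in corpus.molecules:
        specs = by_mol.get(mid, [])
        if len(specs) > cap:
            idx = sorted(rng.integers(0, len(specs), size=cap).tolist())
            specs = [specs[i] for i in idx]
        new_pairs.extend((mid, s) for s in specs)
    return replace(corpus, pairs=new_pairs)


def split_random(corpus: PairedCorpus, ratios: tuple[int, int, int] = (8, 1, 1),
                 seed: int = 0) -> PairedCorpus:
    """Partition molecules (not spectra) into train/val/test at ``ratios``."""
    mids = sorted(corpus.molecules)
    if len(mids) < 10:
        raise ValueError("need at least 10 molecules to split 8:1:1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(mids))
    total = sum(ratios)
    n_train = int(round(len(mids) * ratios[0] / total))
    n_val = int(round(len(mids) * ratios[1] / total))
    splits: dict[str, str] = {}
    for pos, j in enumerate(order):
        if pos < n_train:
            lab = "train"
        elif pos < n_train + n_val:
            lab = "val"
        else:
            lab = "test"
        splits[mids[j]] = lab
    return replace(corpus, splits=splits)


def split_realistic(corpus: PairedCorpus, n_clusters: int = 50,
                    n_train_clusters: int = 29, seed: int = 0) -> PairedCorpus:
    """Structure-based train/test split: MACCS -> 2-D t-SNE -> UPGMA clusters.

    Molecules are embedded by t-SNE on their MACCS keys, clustered by
    UPGMA (average linkage on Euclidean distance in the embedding) into
    ``n_clusters``; the ``n_train_clusters`` largest clusters form the
    training set and the remainder the test set, so test molecules are
    structurally novel relative to training.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from sklearn.manifold import TSNE

    mids = sorted(corpus.molecules)
    if len(mids) <= n_clusters:
        raise ValueError("corpus must have more molecules than clusters")
    X = np.array([corpus.molecules[m].maccs for m in mids], dtype=float)
    perplexity = min(30.0, max(2.0, (len(mids) - 1) / 4))
    emb = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
               init="pca").fit_transform(X)
    Z = linkage(emb, method="average", metric="euclidean")  # UPGMA
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("degenerate clustering: a single cluster holds all molecules")
    # ties in cluster size broken by cluster label for determinism
    order = sorted(zip(-counts, uniq))
    train_clusters = {int(c) for _, c in order[:n_train_clusters]}
    splits = {}
    clusters = {}
    for mid, lab in zip(mids, labels):
        clusters[mid] = int(lab)
        splits[mid] = "train" if int(lab) in train_clusters else "test"
    return replace(corpus, splits=splits, clusters=clusters)


def stratify_by_formula(corpus: PairedCorpus,
                        split: str | None = None) -> dict[str, list[str]]:
    """Group molecule ids by molecular formula (optionally within one split).

    Each stratum is a ready-made candidate set: for a query spectrum of a
    molecule in the stratum, the candidates are all molecules sharing its
    formula. Strata of size 1 give empty candidate sets and are excluded
    from ensemble training by the caller.
    """
    strata: dict[str, list[str]] = {}
    for mid in sorted(corpus.molecules):
        if split is not None and corpus.splits.get(mid) != split:
            continue
        strata.setdefault(corpus.molecules[mid].formula, []).append(mid)
    return strata


# ----------------------------------------------------------------------
# collision-energy normalization
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyNormalizer:
    """Min-max normalizer for collision energies, fit on the training corpus."""

    lo: float
    hi: float

    @classmethod
    def fit(cls, energies: list[float]) -> "EnergyNormalizer":
        if not energies:
            raise ValueError("no energies to fit")
        return cls(lo=float(min(energies)), hi=float(max(energies)))

    def __call__(self, energy: float) -> float:
        if self.hi == self.lo:
            return 0.0
        return float(np.clip((energy - self.lo) / (self.hi - self.lo), 0.0, 1.0))


# ----------------------------------------------------------------------
# file I/O
# ----------------------------------------------------------------------

def read_molecule_table(path: str | Path, fp_bits: int = DEFAULT_FP_BITS,
                        fp_radius: int = DEFAULT_FP_RADIUS) -> list[MoleculeRecord]:
    """Read a CSV/TSV with columns ``id`` and ``smiles``; formula is derived."""
    import pandas as pd

    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("id", "smiles"):
        if col not in df.columns:
            raise ValueError(f"molecule table {path} missing column {col!r}")
    return [parse_molecule(row.smiles, mol_id=str(row.id), fp_bits=fp_bits,
                           fp_radius=fp_radius)
            for row in df.itertuples()]


def read_candidate_table(path: str | Path) -> dict[str, list[str]]:
    """Read an imported candidate CSV with columns ``formula`` and ``smiles``."""
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("formula", "smiles"):
        if col not in df.columns:
            raise ValueError(f"candidate table {path} missing column {col!r}")
    out: dict[str, list[str]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.formula), []).append(str(row.smiles))
    return out


def read_spectra(path: str | Path, dialect: str,
                 precursor_vocabulary: tuple[str, ...] = DEFAULT_PRECURSOR_TYPES,
                 unknown_precursor: str = "skip",
                 energy_normalizer: EnergyNormalizer | None = None,
                 ) -> list[tuple[list[tuple[float, float]], dict]]:
    """Read an MGF or MSP file into (peak list, metadata) records via matchms.

    Metadata holds ``precursor_mz``, ``precursor_type``, ``collision_energy``
    (normalized to [0,1] when a normalizer is supplied, else raw), and the
    source record index. Records whose precursor type is outside the
    vocabulary are skipped (``unknown_precursor='skip'``) or mapped to the
    first vocabulary entry (``'default'``); either way the count is logged.
    """
    from matchms.importing import load_from_mgf, load_from_msp

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect.upper()
    if dialect == "MGF":
        raw = list(load_from_mgf(str(path)))
    elif dialect == "MSP":
        raw = list(load_from_msp(str(path)))
    else:
        raise ValueError(f"unknown spectral dialect {dialect!r}; expected MGF or MSP")

    if not raw:
        logger.warning("read_spectra: %s contains no spectra", path)
        return []

    out = []
    skipped = 0
    for i, sp in enumerate(raw):
        if sp is None:
            raise ValueError(f"malformed spectral record at index {i} in {path}")
        peaks = list(zip(sp.peaks.mz.tolist(), sp.peaks.intensities.tolist()))
        meta = dict(sp.metadata)
        ptype = meta.get("adduct") or meta.get("precursor_type") or meta.get("precursortype")
        if ptype not in precursor_vocabulary:
            if unknown_precursor == "skip":
                skipped += 1
                continue
            ptype = precursor_vocabulary[0]
        energy = meta.get("collision_energy") or meta.get("collisionenergy") or 0.0
        try:
            energy = float(str(energy).strip().rstrip("eV").strip())
        except ValueError:
            energy = 0.0
        if energy_normalizer is not None:
            energy = energy_normalizer(energy)
        pmz = meta.get("precursor_mz") or meta.get("pepmass") or 0.0
        out.append((peaks, {
            "record_index": i,
            "title": meta.get("title") or meta.get("compound_name") or "",
            "precursor_mz": float(pmz) if not isinstance(pmz, tuple) else float(pmz[0]),
            "precursor_type": ptype,
            "collision_energy": energy,
        }))
    if skipped:
        logger.info("read_spectra: skipped %d record(s) with out-of-vocabulary precursor type", skipped)
    return out


# ----------------------------------------------------------------------
# corpus bundle
# ----------------------------------------------------------------------

def save_corpus(corpus: PairedCorpus, out_dir: str | Path, config: dict | None = None) -> None:
    """Write a self-describing corpus bundle (molecule table, spectrum matrix,
    split labels, config snapshot) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    mids = sorted(corpus.molecules)
    pd.DataFrame({
        "id": mids,
        "smiles": [corpus.molecules[m].smiles for m in mids],
        "formula": [corpus.molecules[m].formula for m in mids],
        "split": [corpus.splits.get(m, "") for m in mids],
        "cluster": [corpus.clusters.get(m, -1) for m in mids],
    }).to_csv(out / "molecules.csv", index=False)

    mat = np.array([s.intensities for _, s in corpus.pairs])
    np.save(out / "spectra.npy", mat.astype(np.float32))
    pd.DataFrame({
        "molecule_id": [mid for mid, _ in corpus.pairs],
        "precursor_mz": [s.precursor_mz for _, s in corpus.pairs],
        "collision_energy": [s.setting.collision_energy for _, s in corpus.pairs],
        "precursor_index": [int(np.argmax(s.setting.precursor_onehot)) for _, s in corpus.pairs],
    }).to_csv(out / "spectra_meta.csv", index=False)

    cfg = dict(config or {})
    cfg.setdefault("n_bins", corpus.n_bins)
    cfg.setdefault("n_precursor_types", int(len(corpus.pairs[0][1].setting.precursor_onehot)) if corpus.pairs else 1)
    (out / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))


def load_corpus(bundle_dir: str | Path,
                fp_bits: int = DEFAULT_FP_BITS,
                fp_radius: int = DEFAULT_FP_RADIUS) -> PairedCorpus:
    """Load a corpus bundle written by :func:`save_corpus`."""
    import pandas as pd

    bundle = Path(bundle_dir)
    cfg = json.loads((bundle / "config.json").read_text())
    fp_bits = int(cfg.get("fp_bits", fp_bits))
    fp_radius = int(cfg.get("fp_radius", fp_radius))
    mol_df = pd.read_csv(bundle / "molecules.csv")
    molecules = {}
    splits = {}
    clusters = {}
    for row in mol_df.itertuples():
        rec = parse_molecule(row.smiles, mol_id=str(row.id), fp_bits=fp_bits, fp_radius=fp_radius)
        molecules[rec.id] = rec
        if isinstance(row.split, str) and row.split:
            splits[rec.id] = row.split
        if int(row.cluster) >= 0:
            clusters[rec.id] = int(row.cluster)
    mat = np.load(bundle / "spectra.npy").astype(np.float64)
    meta = pd.read_csv(bundle / "spectra_meta.csv")
    n_ptypes = int(cfg.get("n_precursor_types", 1))
    pairs = []
    for i, row in enumerate(meta.itertuples()):
        onehot = np.zeros(n_ptypes)
        onehot[int(row.precursor_index)] = 1.0
        setting = InstrumentSetting(onehot, float(row.collision_energy))
        pairs.append((str(row.molecule_id),
                      Spectrum(mat[i], float(row.precursor_mz), setting,
                               molecule_id=str(row.molecule_id))))
    return PairedCorpus(molecules=molecules, pairs=pairs, splits=splits,
                        clusters=clusters, n_bins=int(cfg.get("n_bins", DEFAULT_N_BINS)))
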