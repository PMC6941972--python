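"""Desk-scale synthetic world: toy molecules paired with expression-like signatures.

Real training data for this model is L1000-style: a compound library where
each molecule is paired with the z-scored landmark-gene signature it induced
in a cell line, plus knock-out query signatures that have no paired molecule.
The synthetic stand-in keeps the same shape but makes the biology a *known*
function: a molecule acts on the transcriptome only through a small vector
of structural descriptors, which a fixed random projection ``A`` maps to
gene space, plus i.i.d. Gaussian noise:

    signature(molecule) = standardize(A · descriptors(molecule) + ε),
    ε ~ N(0, noise_sd² I).

Because the mapping is descriptor-mediated, "did generation honour the
condition?" is directly measurable: compare the descriptors of generated
molecules with the target descriptor profile behind a query signature.
Query signatures are built from descriptor profiles kept at a minimum
distance from every training molecule's descriptors, mimicking knock-out
conditions whose inducing "compound" is outside the library.

The generator does not attempt realistic transcriptomic covariance,
cell-line effects, or dose–response; see the methods note for what that
implies about test conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import RWMol

from gexmol import grammar as gmr
from gexmol.exceptions import ConfigurationError, SmilesParseError

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "DescriptorVector",
    "SyntheticWorld",
    "QuerySignature",
    "PairedDataset",
    "make_corpus",
    "descriptor_vector",
    "make_signature",
    "make_paired_dataset",
    "canonical_smiles",
]

DESCRIPTOR_NAMES = (
    "heavy_atoms",
    "aromatic_atoms",
    "rings",
    "heteroatoms",
    "branch_points",
)


def canonical_smiles(smiles: str) -> str:
    """Canonical form with stereochemistry and isotopes stripped."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"not a valid molecule: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    return Chem.MolToSmiles(mol, isomericSmiles=False, canonical=True)


# ---------------------------------------------------------------------------
# corpus construction

_VALENCE = {"C": 4, "N": 3, "O": 2}
_RING_CORES = ("c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1")

_COMPLEXITY = {
    "small": dict(min_atoms=2, max_atoms=7, max_subst=2, subst_max=2, p_ring=0.35),
    "medium": dict(min_atoms=2, max_atoms=10, max_subst=3, subst_max=3, p_ring=0.45),
}


def _free_valence(mol: RWMol, idx: int) -> int:
    atom = mol.GetAtomWithIdx(idx)
    if atom.GetIsAromatic():
        cap = 1 if atom.GetTotalNumHs() > 0 else 0
        used = sum(1 for b in atom.GetBonds() if not b.GetIsAromatic())
        return cap - used
    used = int(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))
    return _VALENCE.get(atom.GetSymbol(), 0) - used


def _random_chain(rng: np.random.Generator, n_atoms: int) -> RWMol:
    """Random tree of C/N/O atoms with occasional double bonds."""
    mol = RWMol()
    symbols = ["C", "N", "O"]
    probs = [0.7, 0.15, 0.15]
    mol.AddAtom(Chem.Atom(str(rng.choice(symbols, p=probs))))
    for _ in range(n_atoms - 1):
        candidates = [i for i in range(mol.GetNumAtoms()) if _free_valence(mol, i) >= 1]
        if not candidates:
            break
        parent = int(rng.choice(candidates))
        sym = str(rng.choice(symbols, p=probs))
        new = mol.AddAtom(Chem.Atom(sym))
        double = (
            rng.random() < 0.15
            and _free_valence(mol, parent) >= 2
            and _VALENCE[sym] >= 2
        )
        mol.AddBond(parent, new, Chem.BondType.DOUBLE if double else Chem.BondType.SINGLE)
    return mol


def _random_ring_molecule(rng: np.random.Generator, spec: dict) -> RWMol:
    core = Chem.MolFromSmiles(str(rng.choice(_RING_CORES)))
    mol = RWMol(core)
    n_subst = int(rng.integers(0, spec["max_subst"] + 1))
    for _ in range(n_subst):
        sites = [i for i in range(mol.GetNumAtoms()) if _free_valence(mol, i) >= 1]
        if not sites:
            break
        site = int(rng.choice(sites))
        chain = _random_chain(rng, int(rng.integers(1, spec["subst_max"] + 1)))
        offset = mol.GetNumAtoms()
        combined = RWMol(Chem.CombineMols(mol, chain))
        combined.AddBond(site, offset, Chem.BondType.SINGLE)
        mol = combined
    return mol


def _random_molecule(rng: np.random.Generator, spec: dict) -> str | None:
    try:
        if rng.random() < spec["p_ring"]:
            mol = _random_ring_molecule(rng, spec)
        else:
            n = int(rng.integers(spec["min_atoms"], spec["max_atoms"] + 1))
            mol = _random_chain(rng, n)
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol, isomericSmiles=False, canonical=True)
    except Exception:
        return None


def make_corpus(
    n: int,
    complexity: str = "small",
    seed: int = 0,
    grammar: gmr.GrammarSpec | None = None,
) -> list[str]:
    """Sample ``n`` distinct, grammar-parseable, toolkit-valid SMILES."""
    if n < 1:
        raise ConfigurationError("corpus size must be >= 1")
    if complexity not in _COMPLEXITY:
        raise ConfigurationError(f"unknown complexity {complexity!r}")
    spec = _COMPLEXITY[complexity]
    grammar = grammar or gmr.build_grammar()
    rng = np.random.default_rng(seed)
    corpus: list[str] = []
    seen: set[str] = set()
    stall = 0
    max_stall = 20_000  # consecutive failures => enumeration space exhausted
    while len(corpus) < n and stall < max_stall:
        smi = _random_molecule(rng, spec)
        ok = smi is not None and smi not in seen
        if ok:
            try:
                tokens = gmr.tokenize(smi, grammar)
                ok = gmr._parse_tree(tokens, grammar) is not None
            except SmilesParseError:
                ok = False
        if not ok:
            stall += 1
            continue
        stall = 0
        seen.add(smi)
        corpus.append(smi)
    if len(corpus) < n:
        raise ConfigurationError(
            f"could only enumerate {len(corpus)} distinct molecules at "
            f"complexity={complexity!r}; requested {n}"
        )
    return corpus


# ---------------------------------------------------------------------------
# descriptors and signatures


@dataclass(frozen=True)
class DescriptorVector:
    values: np.ndarray
    names: tuple[str, ...] = DESCRIPTOR_NAMES

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))


def descriptor_vector(smiles: str) -> DescriptorVector:
    """Deterministic structural descriptors of a molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"not a valid molecule: {smiles!r}")
    heavy = mol.GetNumHeavyAtoms()
    aromatic = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    rings = mol.GetRingInfo().NumRings()
    hetero = sum(1 for a in mol.GetAtoms() if a.GetSymbol() not in ("C", "H"))
    branches = sum(1 for a in mol.GetAtoms() if a.GetDegree() >= 3)
    return DescriptorVector(np.array([heavy, aromatic, rings, hetero, branches], float))


def descriptor_matrix(smiles_list: list[str]) -> np.ndarray:
    return np.stack([descriptor_vector(s).values for s in smiles_list])


@dataclass
class SyntheticWorld:
    """Fixed molecule→signature mapping: genes = A · descriptors + noise."""

    projection: np.ndarray  # (n_genes, descriptor_dim)
    noise_sd: float
    corpus: list[str]
    gene_mean: np.ndarray = field(repr=False, default=None)
    gene_sd: np.ndarray = field(repr=False, default=None)

    @property
    def n_genes(self) -> int:
        return int(self.projection.shape[0])

    @property
    def descriptor_dim(self) -> int:
        return int(self.projection.shape[1])

    @classmethod
    def create(
        cls,
        corpus: list[str],
        n_genes: int = 64,
        noise_sd: float = 0.1,
        seed: int = 0,
    ) -> "SyntheticWorld":
        if noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        rng = np.random.default_rng(seed)
        d = len(DESCRIPTOR_NAMES)
        A = rng.normal(size=(n_genes, d)) / np.sqrt(d)
        world = cls(projection=A, noise_sd=float(noise_sd), corpus=list(corpus))
        raw = descriptor_matrix(corpus) @ A.T  # noiseless corpus signatures
        world.gene_mean = raw.mean(axis=0)
        world.gene_sd = raw.std(axis=0)
        world.gene_sd[world.gene_sd < 1e-12] = 1.0
        return world

    def signature_from_descriptors(
        self, descriptors: np.ndarray, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Standardized signature for an arbitrary descriptor profile."""
        descriptors = np.asarray(descriptors, dtype=np.float64)
        if descriptors.shape != (self.descriptor_dim,):
            raise ConfigurationError(
                f"descriptor profile must have length {self.descriptor_dim}"
            )
        raw = self.projection @ descriptors
        if self.noise_sd > 0 and rng is not None:
            raw = raw + rng.normal(scale=self.noise_sd, size=self.n_genes)
        return (raw - self.gene_mean) / self.gene_sd


def make_signature(smiles: str, world: SyntheticWorld, seed: int = 0) -> np.ndarray:
    """Signature induced by a molecule: standardized A·descriptors + noise."""
    rng = np.random.default_rng(seed)
    return world.signature_from_descriptors(descriptor_vector(smiles).values, rng)


# ---------------------------------------------------------------------------
# paired dataset + knock-out-like queries


@dataclass(frozen=True)
class QuerySignature:
    """A condition with no paired molecule; targets kept as ground truth."""

    signature: np.ndarray
    target_descriptors: np.ndarray


@dataclass
class PairedDataset:
    smiles: list[str]
    signatures: np.ndarray  # (n, n_genes)
    queries: list[QuerySignature]

    def __len__(self):
        return len(self.smiles)


def make_paired_dataset(
    world: SyntheticWorld,
    seed: int = 0,
    n_queries: int = 20,
    query_margin: float = 0.5,
) -> PairedDataset:
    """Per-corpus-molecule signatures plus held-out query signatures.

    Query target profiles are mixtures of two corpus descriptor vectors with
    jitter, rejected unless they sit at least ``query_margin`` (in z-scored
    descriptor space) from every training profile — knock-out-like
    conditions whose "compound" is outside the library.
    """
    ss = np.random.SeedSequence(seed)
    sig_rng, query_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    desc = descriptor_matrix(world.corpus)
    signatures = np.stack(
        [world.signature_from_descriptors(d, sig_rng) for d in desc]
    )

    d_mean = desc.mean(axis=0)
    d_sd = desc.std(axis=0)
    d_sd[d_sd < 1e-12] = 1.0
    desc_z = (desc - d_mean) / d_sd

    queries: list[QuerySignature] = []
    attempts = 0
    while len(queries) < n_queries and attempts < 2000 * n_queries:
        attempts += 1
        i, j = query_rng.integers(0, len(desc), size=2)
        lam = query_rng.uniform(0.2, 0.8)
        target = lam * desc[i] + (1 - lam) * desc[j]
        target = np.clip(target + query_rng.normal(scale=0.5, size=desc.shape[1]), 0, None)
        target_z = (target - d_mean) / d_sd
        gap = np.sqrt(((desc_z - target_z) ** 2).sum(axis=1)).min()
        if gap < query_margin:
            continue
        sig = world.signature_from_descriptors(target, query_rng)
        queries.append(QuerySignature(signature=sig, target_descriptors=target))
    if len(queries) < n_queries:
        raise ConfigurationError(
            f"could not place {n_queries} queries at margin {query_margin}"
        )
    return PairedDataset(smiles=list(world.corpus), signatures=signatures, queries=queries)
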