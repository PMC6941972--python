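"""Result-side computations: generation at scale and all evaluation metrics.

Covers the full downstream protocol: per-signature generation with
validity / uniqueness / synthesizability accounting, the synthetic-
accessibility filter (Ertl–Schuffenhauer SA score < 4.5), fingerprint and
fragment similarity (Tanimoto over MACCS keys or Morgan fingerprints with
radius 3 and 1024 bits, and Fraggle similarity), Murcko scaffold overlap,
the expression-signature nearest-neighbour search baseline (Euclidean or
cosine), the conditional classification-score comparison with a one-sided
Mann–Whitney U-test, and scaffold optimization through the stage-II
generator.

Validity means the decoded SMILES survives toolkit sanitization; uniqueness
is counted over canonical SMILES of the valid molecules.
"""

from __future__ import annotations

import logging
import os
import sys
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import AllChem, MACCSkeys, DataStructs
from rdkit.Chem.Fraggle import FraggleSim
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy.stats import mannwhitneyu

from gexmol.exceptions import ConfigurationError, ShapeError, SmilesParseError

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib implementation of the SA score)

logger = logging.getLogger(__name__)

__all__ = [
    "GenerationReport",
    "SimilarityRecord",
    "generate_for_signature",
    "sa_score",
    "sa_filter",
    "similarity",
    "max_similarity_to_set",
    "scaffold_overlap",
    "signature_nn_search",
    "classification_score_compare",
    "optimize_scaffold",
]

SA_THRESHOLD = 4.5
MORGAN_RADIUS = 3
MORGAN_BITS = 1024
METRICS = ("maccs", "morgan", "fraggle")


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"not a valid molecule: {smiles!r}")
    return mol


# ---------------------------------------------------------------------------
# generation


@dataclass
class GenerationReport:
    """Per-signature generation accounting: generated ≥ valid ≥ unique."""

    generated: int
    valid: int
    unique_valid: int
    synthesizable: int
    smiles: list[str] = field(default_factory=list)  # valid decoded molecules
    unique_smiles: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (self.generated >= self.valid >= self.unique_valid >= 0):
            raise ValueError("count chain generated >= valid >= unique violated")
        if self.synthesizable > self.valid:
            raise ValueError("synthesizable cannot exceed valid")

    @property
    def valid_fraction(self) -> float:
        return self.valid / self.generated if self.generated else 0.0

    @property
    def unique_fraction(self) -> float:
        return self.unique_valid / self.generated if self.generated else 0.0

    @property
    def synthesizable_fraction(self) -> float:
        return self.synthesizable / self.generated if self.generated else 0.0


def generate_for_signature(
    signature: np.ndarray,
    n: int,
    gan_results,
    translator_results,
    stage: int = 2,
    seed: int = 0,
) -> GenerationReport:
    """Generate ``n`` molecules for one condition and report the count chain.

    Latents come from the requested GAN stage (default: the refined stage-II
    output G1(G0(z, c), c)), are decoded with the grammar-masked translator,
    and judged valid by toolkit sanitization.  The full-scale protocol is
    n = 1000 per signature.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    latents = gan_results.generate_latents(
        signature, n_per_signature=n, stage=stage, seed=seed
    )[0]
    decoded = translator_results.decode_batch(latents)
    valid: list[str] = []
    for smi in decoded:
        if smi is None:
            continue
        mol = Chem.MolFromSmiles(smi)
        if mol is not None:
            valid.append(Chem.MolToSmiles(mol, isomericSmiles=False))
    unique = list(dict.fromkeys(valid))
    synthesizable = [s for s in valid if sa_score(s) < SA_THRESHOLD]
    return GenerationReport(
        generated=n,
        valid=len(valid),
        unique_valid=len(unique),
        synthesizable=len(synthesizable),
        smiles=valid,
        unique_smiles=unique,
    )


# ---------------------------------------------------------------------------
# synthetic accessibility


def sa_score(smiles: str) -> float:
    """Ertl–Schuffenhauer synthetic-accessibility score (1 easy … 10 hard)."""
    return float(sascorer.calculateScore(_mol(smiles)))


def sa_filter(smiles_list: list[str], threshold: float = SA_THRESHOLD) -> list[str]:
    """Keep molecules with SA score below the threshold; skip unparseable ones."""
    kept = []
    for smi in smiles_list:
        try:
            if sa_score(smi) < threshold:
                kept.append(smi)
        except SmilesParseError:
            logger.warning("sa_filter: skipping unparseable SMILES %r", smi)
    return kept


# ---------------------------------------------------------------------------
# similarity


@dataclass(frozen=True)
class SimilarityRecord:
    query: str
    reference: str
    metric: str
    value: float

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ConfigurationError(f"unknown metric {self.metric!r}")
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"similarity {self.value} outside [0, 1]")


def _fingerprint(mol: Chem.Mol, metric: str):
    if metric == "maccs":
        return MACCSkeys.GenMACCSKeys(mol)
    return AllChem.GetMorganFingerprintAsBitVect(mol, MORGAN_RADIUS, nBits=MORGAN_BITS)


def similarity(query: str, reference: str, metric: str = "maccs") -> SimilarityRecord:
    """Pairwise molecular similarity in [0, 1] under the chosen metric."""
    if metric not in METRICS:
        raise ConfigurationError(f"unknown metric {metric!r}; choose from {METRICS}")
    mq, mr = _mol(query), _mol(reference)
    if metric == "fraggle":
        value, _ = FraggleSim.GetFraggleSimilarity(mq, mr)
    else:
        value = DataStructs.TanimotoSimilarity(
            _fingerprint(mq, metric), _fingerprint(mr, metric)
        )
    return SimilarityRecord(query=query, reference=reference, metric=metric, value=float(value))


def max_similarity_to_set(
    query: str, actives: list[str], metric: str = "maccs"
) -> SimilarityRecord:
    """Most similar active (ties broken by first occurrence)."""
    if not actives:
        raise ConfigurationError("actives list must be nonempty")
    best = None
    for ref in actives:
        rec = similarity(query, ref, metric)
        if best is None or rec.value > best.value:
            best = rec
    return best


# ---------------------------------------------------------------------------
# scaffolds


def _scaffold(smiles: str, generic: bool) -> str | None:
    try:
        mol = _mol(smiles)
    except SmilesParseError:
        logger.warning("scaffold_overlap: skipping unparseable SMILES %r", smiles)
        return None
    scaf = MurckoScaffold.GetScaffoldForMol(mol)
    if scaf is None or scaf.GetNumAtoms() == 0:
        return ""
    if generic:
        scaf = MurckoScaffold.MakeScaffoldGeneric(scaf)
    return Chem.MolToSmiles(scaf, isomericSmiles=False)


def scaffold_overlap(
    generated: list[str], actives: list[str], generic: bool = False
) -> tuple[int, list[str]]:
    """Count Murcko scaffolds shared between two molecule sets.

    ``generic=True`` abstracts all atoms to carbon and all bonds to single
    before comparison.  Returns (overlap count, sorted shared scaffolds);
    acyclic molecules (empty scaffold) are ignored.
    """
    gen_scafs = {s for s in (_scaffold(x, generic) for x in generated) if s}
    act_scafs = {s for s in (_scaffold(x, generic) for x in actives) if s}
    shared = sorted(gen_scafs & act_scafs)
    return len(shared), shared


# ---------------------------------------------------------------------------
# signature similarity search


def signature_nn_search(
    query: np.ndarray,
    library_signatures: np.ndarray,
    metric: str = "euclidean",
) -> tuple[int, float]:
    """Index and distance of the library signature nearest to the query.

    Cosine distance is 1 − cosine similarity; ties break to the first
    occurrence (argmin).
    """
    query = np.asarray(query, dtype=np.float64).ravel()
    lib = np.atleast_2d(np.asarray(library_signatures, dtype=np.float64))
    if lib.shape[0] == 0:
        raise ConfigurationError("library must be nonempty")
    if lib.shape[1] != query.shape[0]:
        raise ShapeError(
            f"query dim {query.shape[0]} != library dim {lib.shape[1]}"
        )
    if metric == "euclidean":
        dists = np.sqrt(((lib - query) ** 2).sum(axis=1))
    elif metric == "cosine":
        qn = np.linalg.norm(query)
        ln = np.linalg.norm(lib, axis=1)
        denom = np.where(qn * ln > 0, qn * ln, 1.0)
        dists = 1.0 - (lib @ query) / denom
    else:
        raise ConfigurationError(f"unknown metric {metric!r}")
    idx = int(np.argmin(dists))
    return idx, float(dists[idx])


# ---------------------------------------------------------------------------
# classification-score comparison


def classification_score_compare(
    latents_a: np.ndarray,
    conditions_a: np.ndarray,
    latents_b: np.ndarray,
    conditions_b: np.ndarray,
    conditional_net,
) -> dict:
    """Conditional-net scores of two sets and a one-sided rank test (A > B).

    Higher classification score means the condition is better fulfilled.
    Exact Mann–Whitney enumeration for group sizes ≤ 8 without ties, normal
    approximation with tie and continuity correction otherwise.
    """
    from gexmol.autodiff import no_grad

    latents_a, latents_b = np.atleast_2d(latents_a), np.atleast_2d(latents_b)
    conditions_a, conditions_b = np.atleast_2d(conditions_a), np.atleast_2d(conditions_b)
    if latents_a.shape[0] == 0 or latents_b.shape[0] == 0:
        raise ConfigurationError("both sets must be nonempty")
    with no_grad():
        scores_a = conditional_net(latents_a, conditions_a).data.ravel()
        scores_b = conditional_net(latents_b, conditions_b).data.ravel()
    u_stat, p_value = mann_whitney_u_greater(scores_a, scores_b)
    return {
        "scores_a": scores_a,
        "scores_b": scores_b,
        "median_a": float(np.median(scores_a)),
        "median_b": float(np.median(scores_b)),
        "u_statistic": u_stat,
        "p_value": p_value,
    }


def mann_whitney_u_greater(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """One-sided Mann–Whitney U test that ``a`` is stochastically greater."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# scaffold optimization (stage II on an encoded scaffold)


def optimize_scaffold(
    scaffold: str,
    signature: np.ndarray,
    gan_results,
    translator_results,
) -> str:
    """Refine a scaffold toward a condition: encode → G1(latent, c) → decode.

    Deterministic (argmax decoding); the scaffold is canonicalized first.
    """
    from gexmol.synthetic import canonical_smiles

    smi = canonical_smiles(scaffold)
    latent = translator_results.encode(smi)
    refined = gan_results.refine_latents(latent, signature)[0]
    return translator_results.decode(refined, mode="argmax")
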