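"""Significant-interaction-pattern libraries from Bayesian Gaussian mixtures.

Training pools interaction pairs from many protein-ligand complexes,
groups them by (SYBYL type, fragment type), and fits each group's
local-frame contact geometries with a variational Bayesian Gaussian
mixture (Dirichlet-process weight prior, full covariances).  Mixture
components to which at least ``min_members`` training ligand atoms are
hard-assigned (argmax responsibility) are flagged *significant
interaction patterns*; a docked pair later counts toward a pose's
pattern statistics exactly when its argmax component is significant.

Member counts are recomputed from the stored Gaussian parameters
(weighted log-density argmax) rather than taken from the variational
predictive, so a serialized library reproduces the fit-time assignment
rule bit for bit.
"""

from __future__ import annotations

import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
from scipy.stats import chi2
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import BayesianGaussianMixture

from .chem_typing import (
    FRAGMENT_ORIENTATION_CONVENTION,
    SYBYL_TABLE_VERSION,
    assign_sybyl_types,
    enumerate_fragments,
    perceive_bonds,
)
from .complex_io import ComplexStructure, strip_hydrogens
from .contacts import (
    FRAME_CONVENTION,
    GroupKey,
    InteractionPair,
    extract_interaction_pairs,
    group_pairs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LibraryParams",
    "LibrarySchemaError",
    "PatternComponent",
    "PatternLibrary",
    "assign_pair",
    "build_pattern_library",
    "derive_group_seed",
    "fit_group_bgmm",
    "load_library",
    "save_library",
]

SCHEMA_VERSION = "posefilter-library-1"

_COVARIANCE_REG = 1e-4  # A^2 added to covariance diagonals


class LibrarySchemaError(ValueError):
    """Serialized library schema does not match this implementation."""


@dataclass
class PatternComponent:
    """One fitted Gaussian of a contact group's mixture."""

    group_key: GroupKey
    mean: np.ndarray
    covariance: np.ndarray
    weight: float
    member_count: int
    significant: bool

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(3)
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(3, 3)
        if np.linalg.eigvalsh(self.covariance).min() <= 0:
            raise ValueError("component covariance must be positive definite")
        if not 0.0 <= self.weight <= 1.0 + 1e-6:
            raise ValueError("mixture weight must lie in [0, 1]")


@dataclass
class LibraryParams:
    """Training-time configuration recorded in the library metadata."""

    cutoff: float = 5.0
    min_members: int = 20
    max_components: int = 10
    seed: int = 0
    bond_mode: str = "distance"
    mahalanobis_gate: bool = False


@dataclass
class PatternLibrary:
    components: dict[GroupKey, list[PatternComponent]]
    metadata: dict = field(default_factory=dict)

    def significant_components(self) -> list[PatternComponent]:
        return [c for comps in self.components.values() for c in comps if c.significant]


def derive_group_seed(master_seed: int, group_key: GroupKey) -> int:
    """Per-group RNG seed: CRC-32 of the canonical key string XOR master, mod 2^31."""
    canonical = "|".join([group_key[0], *group_key[1]])
    return (zlib.crc32(canonical.encode("utf-8")) ^ (master_seed & 0x7FFFFFFF)) % (2**31)


def _weighted_log_prob(points: np.ndarray, weights: np.ndarray,
                       means: np.ndarray, covariances: np.ndarray) -> np.ndarray:
    """log(w_k) + log N(x | mu_k, Sigma_k), shape (n_points, n_components)."""
    n, k = len(points), len(weights)
    out = np.empty((n, k))
    for idx in range(k):
        cov = covariances[idx]
        chol = np.linalg.cholesky(cov)
        diff = points - means[idx]
        sol = np.linalg.solve(chol, diff.T)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[:, idx] = (
            np.log(max(weights[idx], 1e-300))
            - 0.5 * (3 * np.log(2 * np.pi) + logdet + maha)
        )
    return out


def _fit_group(
    points: np.ndarray,
    group_key: GroupKey,
    max_components: int,
    seed: int,
    min_members: int,
) -> tuple[list[PatternComponent], bool]:
    n = len(points)
    if n == 0:
        raise ValueError("cannot fit a mixture to an empty group")
    if n == 1:
        comp = PatternComponent(
            group_key=group_key,
            mean=points[0],
            covariance=np.eye(3) * _COVARIANCE_REG,
            weight=1.0,
            member_count=1,
            significant=1 >= min_members,
        )
        return [comp], True
    # At least two points per component; singleton components collapse to
    # ill-defined covariances.
    n_components = max(1, min(max_components, n // 2))
    model = BayesianGaussianMixture(
        n_components=n_components,
        covariance_type="full",
        weight_concentration_prior_type="dirichlet_process",
        # The sklearn default mean_precision_prior (1.0) shrinks component
        # means toward the global centroid hard enough to merge clusters
        # separated by many sigma; a weakly-informative prior keeps
        # well-separated patterns distinct.
        mean_precision_prior=1e-2,
        reg_covar=_COVARIANCE_REG,
        tol=1e-3,
        max_iter=500,
        n_init=10,
        random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            model.fit(points)
        except (ValueError, np.linalg.LinAlgError):
            # Collapsed samples can defeat the default regularization on
            # tiny or degenerate groups; refit stiffer, then fall back to
            # a single moment-matched Gaussian.
            try:
                model.set_params(reg_covar=1e-2)
                model.fit(points)
            except (ValueError, np.linalg.LinAlgError):
                mean = points.mean(axis=0)
                cov = np.cov(points.T, bias=True).reshape(3, 3) + 1e-2 * np.eye(3)
                comp = PatternComponent(
                    group_key=group_key, mean=mean, covariance=cov,
                    weight=1.0, member_count=n, significant=n >= min_members,
                )
                return [comp], False
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    log_prob = _weighted_log_prob(points, model.weights_, model.means_, model.covariances_)
    hard = np.argmax(log_prob, axis=1)
    counts = np.bincount(hard, minlength=n_components)
    comps = [
        PatternComponent(
            group_key=group_key,
            mean=model.means_[k],
            covariance=model.covariances_[k],
            weight=float(model.weights_[k]),
            member_count=int(counts[k]),
            significant=bool(counts[k] >= min_members),
        )
        for k in range(n_components)
    ]
    return comps, converged


def fit_group_bgmm(
    points: Sequence[Sequence[float]] | np.ndarray,
    max_components: int = 10,
    seed: int = 0,
    min_members: int = 20,
    group_key: GroupKey = ("Du", ("UNK", "X1", "X2", "X3")),
) -> list[PatternComponent]:
    """Fit one contact group's 3-D point cloud with a variational BGMM.

    Components are populated with hard-assignment member counts; a
    component is significant iff at least ``min_members`` points argmax
    to it, so groups smaller than ``min_members`` can never produce a
    significant pattern.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    comps, _ = _fit_group(pts, group_key, max_components, seed, min_members)
    return comps


def extract_complex_pairs(
    structure: ComplexStructure,
    cutoff: float = 5.0,
    bond_mode: str = "distance",
) -> list[InteractionPair]:
    """Full preparation pipeline for one complex: strip H, perceive bonds,
    type ligand atoms, enumerate fragments, extract pairs."""
    heavy = strip_hydrogens(structure)
    ligand_bonds = heavy.ligand_bonds or perceive_bonds(heavy.ligand_atoms, "distance")
    protein_bonds = heavy.protein_bonds or perceive_bonds(heavy.protein_atoms, bond_mode)
    types = assign_sybyl_types(heavy.ligand_atoms, ligand_bonds)
    fragments = enumerate_fragments(heavy.protein_atoms, protein_bonds)
    return extract_interaction_pairs(heavy, types, fragments, cutoff=cutoff)


def build_pattern_library(
    training_complexes: Iterable[ComplexStructure],
    params: LibraryParams | None = None,
) -> PatternLibrary:
    """Extract, pool, group and fit interaction pairs from training complexes.

    Deterministic given the master seed and input order: groups are fitted
    in sorted key order with per-group seeds from :func:`derive_group_seed`.
    Complexes whose preparation fails are skipped with a logged identifier.
    """
    params = params or LibraryParams()
    pooled: list[InteractionPair] = []
    n_complexes = 0
    source_ids: list[str] = []
    for structure in training_complexes:
        n_complexes += 1
        try:
            pooled.extend(
                extract_complex_pairs(structure, params.cutoff, params.bond_mode)
            )
            source_ids.append(structure.source_id or f"complex-{n_complexes}")
        except Exception:
            logger.exception("skipping complex %r", structure.source_id)
    if n_complexes == 0:
        raise ValueError("at least one training complex is required")
    if not pooled:
        raise ValueError("no interaction pairs extracted from the training set")

    groups = group_pairs(pooled)
    components: dict[GroupKey, list[PatternComponent]] = {}
    unconverged: list[str] = []
    for key in sorted(groups):
        pts = np.array([p.local_coords for p in groups[key]])
        comps, converged = _fit_group(
            pts, key, params.max_components,
            derive_group_seed(params.seed, key), params.min_members,
        )
        if not converged:
            unconverged.append(_key_to_str(key))
        components[key] = comps

    metadata = {
        "schema_version": SCHEMA_VERSION,
        "cutoff": params.cutoff,
        "min_members": params.min_members,
        "max_components": params.max_components,
        "seed": params.seed,
        "bond_mode": params.bond_mode,
        "frame_convention": FRAME_CONVENTION,
        "fragment_orientation_convention": FRAGMENT_ORIENTATION_CONVENTION,
        "sybyl_table_version": SYBYL_TABLE_VERSION,
        "training_set": {
            "n_complexes": n_complexes,
            "n_pairs": len(pooled),
            "source_ids": source_ids,
        },
        "unconverged_groups": unconverged,
    }
    return PatternLibrary(components=components, metadata=metadata)


_MAHALANOBIS_GATE = float(chi2.ppf(0.99, df=3))


def assign_pair(
    pair: InteractionPair,
    library: PatternLibrary,
    mahalanobis_gate: bool | None = None,
) -> bool:
    """Is a docked interaction pair a significant interaction pattern?

    False when the pair's group is absent from the library; otherwise the
    pair is hard-assigned to the argmax-responsibility component of the
    group's mixture and inherits that component's significance flag.  The
    optional Mahalanobis gate (chi-square 3-dof 0.99 quantile) additionally
    requires the point to lie inside the component's high-density region;
    it is off by default.
    """
    comps = library.components.get(pair.group_key)
    if not comps:
        return False
    if mahalanobis_gate is None:
        mahalanobis_gate = bool(library.metadata.get("mahalanobis_gate", False))
    point = np.asarray(pair.local_coords, dtype=float).reshape(1, 3)
    weights = np.array([c.weight for c in comps])
    means = np.array([c.mean for c in comps])
    covs = np.array([c.covariance for c in comps])
    log_prob = _weighted_log_prob(point, weights, means, covs)
    k = int(np.argmax(log_prob[0]))
    if not comps[k].significant:
        return False
    if mahalanobis_gate:
        diff = point[0] - comps[k].mean
        maha = float(diff @ np.linalg.solve(comps[k].covariance, diff))
        if maha > _MAHALANOBIS_GATE:
            return False
    return True


def _key_to_str(key: GroupKey) -> str:
    return "|".join([key[0], *key[1]])


def _key_from_str(text: str) -> GroupKey:
    parts = text.split("|")
    if len(parts) != 5:
        raise LibrarySchemaError(f"malformed group key {text!r}")
    return (parts[0], tuple(parts[1:]))  # type: ignore[return-value]


def save_library(library: PatternLibrary, stream: TextIO) -> None:
    """Serialize a library to schema-versioned JSON (full float precision)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "metadata": library.metadata,
        "groups": {
            _key_to_str(key): [
                {
                    "mean": comp.mean.tolist(),
                    "covariance": comp.covariance.tolist(),
                    "weight": comp.weight,
                    "member_count": comp.member_count,
                    "significant": comp.significant,
                }
                for comp in comps
            ]
            for key, comps in sorted(library.components.items())
        },
    }
    json.dump(doc, stream, indent=1, sort_keys=True)


def load_library(stream: TextIO) -> PatternLibrary:
    """Inverse of :func:`save_library`; refuses mismatched schema versions."""
    try:
        doc = json.load(stream)
    except json.JSONDecodeError as exc:
        raise LibrarySchemaError(f"library document is not valid JSON: {exc}") from exc
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise LibrarySchemaError(
            f"library schema {version!r} does not match expected {SCHEMA_VERSION!r}"
        )
    components: dict[GroupKey, list[PatternComponent]] = {}
    for key_str, comps in doc["groups"].items():
        key = _key_from_str(key_str)
        components[key] = [
            PatternComponent(
                group_key=key,
                mean=np.array(c["mean"]),
                covariance=np.array(c["covariance"]),
                weight=c["weight"],
                member_count=c["member_count"],
                significant=c["significant"],
            )
            for c in comps
        ]
    return PatternLibrary(components=components, metadata=doc["metadata"])
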