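"""Synthetic RPKM matrices with planted coexpression structure.

The generator emulates the statistical shape the analysis assumes: an
ordered developmental gradient (4 zones by default) carrying two
anti-correlated prototype profiles — ``early`` (monotone decreasing, high in
young tissue) and ``late`` (monotone increasing) — with

* *module genes*: prototype x gene-specific positive scale x per-zone
  multiplicative log-normal noise (``noise_sd`` on the log2 scale, default
  0.05);
* *transporter genes*: generated from a chosen prototype the same way, so
  each transporter's planted association partners are exactly the module
  genes of its prototype;
* *background genes*: independent per-zone log-normal values, uncorrelated
  with everything by construction.

RPKM magnitudes span roughly 1-1000, as real gradient profiles do.  Output
is deterministic for a given spec + seed, and every generated gene carries a
ground-truth label so module recovery and association mining can be scored
without external data.

``perturb_gene`` rebuilds one gene's profile at an exactly prescribed
Pearson correlation to a reference gene, which is how threshold behaviour
around min_cc is probed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog_io import ExpressionTable
from .errors import CalibrationError, GeneLookupError, ParameterError

__all__ = ["SyntheticSpec", "GroundTruth", "simulate_expression", "perturb_gene",
           "write_ground_truth"]

BACKGROUND = "background"


def _default_prototypes(n_zones: int) -> list[np.ndarray]:
    """Early (monotone decreasing) and late (monotone increasing) profiles."""
    late = np.geomspace(2.0, 500.0, n_zones)
    return [late[::-1].copy(), late]


@dataclass
class SyntheticSpec:
    """Study-shaped generator settings (defaults mirror the 4-zone design)."""

    n_zones: int = 4
    prototypes: list | None = None
    module_sizes: tuple[int, ...] = (10, 10)
    n_transporters_per_prototype: int = 5
    n_background: int = 20
    noise_sd: float = 0.05  # log2-scale multiplicative noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_zones < 2:
            raise ParameterError("n_zones must be >= 2")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.n_transporters_per_prototype < 0 or self.n_background < 0:
            raise ParameterError("gene counts must be >= 0")
        if any(s < 0 for s in self.module_sizes):
            raise ParameterError("module sizes must be >= 0")
        if self.prototypes is None:
            self.prototypes = _default_prototypes(self.n_zones)
        self.prototypes = [np.asarray(p, dtype=float) for p in self.prototypes]
        for p in self.prototypes:
            if p.shape != (self.n_zones,):
                raise ParameterError("each prototype must have one value per zone")
            if (p < 0).any():
                raise ParameterError("prototype RPKM must be >= 0")
        if len(self.module_sizes) != len(self.prototypes):
            raise ParameterError("module_sizes must match number of prototypes")


@dataclass
class GroundTruth:
    """Planted labels: prototype index per structured gene, background else.

    ``labels`` maps every generated gene_id to a prototype index (int) or
    ``"background"``; ``roles`` distinguishes module members from
    transporters so query/target sets can be reconstructed.
    """

    labels: dict[str, int | str] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)

    def module_genes(self, prototype: int | None = None) -> list[str]:
        return [
            g
            for g, r in self.roles.items()
            if r == "module" and (prototype is None or self.labels[g] == prototype)
        ]

    def transporter_genes(self, prototype: int | None = None) -> list[str]:
        return [
            g
            for g, r in self.roles.items()
            if r == "transporter"
            and (prototype is None or self.labels[g] == prototype)
        ]

    def background_genes(self) -> list[str]:
        return [g for g, r in self.roles.items() if r == BACKGROUND]


def _zone_labels(n_zones: int) -> list[str]:
    base = ["basal", "transitional", "maturing", "mature"]
    if n_zones <= len(base):
        return base[:n_zones]
    return base + [f"zone{i}" for i in range(len(base) + 1, n_zones + 1)]


def simulate_expression(spec: SyntheticSpec) -> tuple[ExpressionTable, GroundTruth]:
    """Draw one synthetic RPKM matrix plus its ground truth.

    Deterministic: the same spec and seed give a bit-identical matrix.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    truth = GroundTruth()

    def scaled_copy(proto: np.ndarray) -> np.ndarray:
        scale = float(2.0 ** rng.uniform(-2.0, 2.0))
        noise = 2.0 ** rng.normal(0.0, spec.noise_sd, spec.n_zones)
        return proto * scale * noise

    for p, (proto, size) in enumerate(zip(spec.prototypes, spec.module_sizes)):
        for i in range(size):
            gid = f"MOD{p}_G{i:03d}"
            gene_ids.append(gid)
            rows.append(scaled_copy(proto))
            truth.labels[gid] = p
            truth.roles[gid] = "module"
    for p, proto in enumerate(spec.prototypes):
        for i in range(spec.n_transporters_per_prototype):
            gid = f"TRN{p}_T{i:03d}"
            gene_ids.append(gid)
            rows.append(scaled_copy(proto))
            truth.labels[gid] = p
            truth.roles[gid] = "transporter"
    for i in range(spec.n_background):
        gid = f"BG_G{i:03d}"
        gene_ids.append(gid)
        rows.append(2.0 ** rng.normal(4.0, 2.0, spec.n_zones))
        truth.labels[gid] = BACKGROUND
        truth.roles[gid] = BACKGROUND

    values = pd.DataFrame(
        np.asarray(rows, dtype=float) if rows else np.empty((0, spec.n_zones)),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=_zone_labels(spec.n_zones),
    )
    if len(values) == 0:
        raise ParameterError("spec generates no genes")
    return ExpressionTable(values, list(gene_ids)), truth


def perturb_gene(
    table: ExpressionTable,
    gene_id: str,
    target_cc: float,
    reference_id: str,
    seed: int = 0,
) -> ExpressionTable:
    """Replace one gene's profile so its Pearson cc to a reference is exact.

    Construction: in the centered profile space, mix the standardized
    reference direction (weight ``target_cc``) with a random orthogonal
    direction (weight sqrt(1 - target_cc^2)); the sample correlation of the
    result with the reference equals ``target_cc`` exactly.  The profile is
    then shifted/scaled (correlation-invariant) back to non-negative RPKM
    at the reference's magnitude.  Raises :class:`CalibrationError` when the
    reference profile is flat (no correlation is defined against it).
    """
    if not -1.0 <= target_cc <= 1.0:
        raise ParameterError(f"target_cc must be in [-1, 1], got {target_cc}")
    for g in (gene_id, reference_id):
        if g not in table.values.index:
            raise GeneLookupError(f"gene_id {g!r} not in expression table")
    ref = table.row(reference_id)
    n = ref.size
    u = ref - ref.mean()
    norm = float(np.linalg.norm(u))
    if norm == 0.0:
        raise CalibrationError(
            f"reference {reference_id!r} has zero variance; no target "
            "correlation is achievable"
        )
    u /= norm
    rng = np.random.default_rng(seed)
    v = np.zeros(n)
    for _ in range(64):  # essentially always succeeds on the first draw
        w = rng.normal(size=n)
        w -= w.mean()
        w -= (w @ u) * u
        wn = float(np.linalg.norm(w))
        if wn > 1e-12:
            v = w / wn
            break
    else:
        raise CalibrationError("could not draw an orthogonal direction")
    z = target_cc * u + math.sqrt(max(0.0, 1.0 - target_cc**2)) * v
    # affine map with positive slope preserves the correlation; anchor the
    # magnitude to the reference and keep RPKM non-negative
    scale = float(ref.std()) or 1.0
    y = z * scale * math.sqrt(n)
    y = y - y.min() + 0.01 * scale
    new = table.copy()
    idx = [i for i, g in enumerate(new.values.index) if g == gene_id]
    for i in idx:
        new.values.iloc[i] = y
        new.below_detection.iloc[i] = False
    new.validate()
    return new


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Ground-truth TSV: gene_id, label (prototype index or background), role."""
    lines = ["gene_id\tlabel\trole"]
    for gid, label in truth.labels.items():
        lines.append(f"{gid}\t{label}\t{truth.roles[gid]}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
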