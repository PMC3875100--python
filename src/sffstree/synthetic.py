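"""Two-class expression simulator with known ground truth.

Emulates the data regime the pipeline targets: probes x samples log2
intensities, Gaussian homoscedastic background (the simplest model consistent
with normalized log2 microarray signal), and planted markers of four roles:

``single_marker``
    shifted +effect*sigma in every tumor sample — a clean overexpressed
    biomarker separable on its own;
``down_marker``
    shifted -effect*sigma in every tumor sample — an underexpressed marker
    (useful for exercising the direction filter);
``pair_A`` / ``pair_B``
    a complementary pair: A is shifted in a seeded random tumor subset of
    size round(coverage * n_tumor), B in exactly the complementary tumor
    subset. Neither gene alone separates all tumors, but together they
    support a perfectly separating depth-2 tree — the motif of two markers
    that must be used jointly.

Everything is reproducible from the spec seed; the returned truth object
records each planted probe's role, effect and shifted sample subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .expr_io import ExpressionDataset

ROLES = ("single_marker", "pair_A", "pair_B", "down_marker")


@dataclass(frozen=True)
class PlantedProbe:
    """One planted marker: its role, effect size (in background-sigma units)
    and, for pair roles, the tumor coverage fraction of the A gene."""

    role: str
    effect: float
    coverage: float = 0.9

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown planted role {self.role!r}")
        if self.effect <= 0:
            raise ValidationError("effect must be positive (in sigma units)")
        if not 0.0 < self.coverage < 1.0:
            raise ValidationError("coverage must lie strictly in (0, 1)")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of a simulated dataset.

    Defaults encode the canonical desk-scale scenario used throughout the
    test suite: 30 tumor / 30 normal samples, 500 probes, background
    log2 intensity 8.0 +/- 1.0.
    """

    n_tumor: int = 30
    n_normal: int = 30
    n_probes: int = 500
    planted: tuple[PlantedProbe, ...] = ()
    mu_bg: float = 8.0
    sigma_bg: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted", tuple(self.planted))
        if self.n_tumor < 1 or self.n_normal < 1:
            raise ValidationError("need at least one sample per class")
        if self.n_probes < len(self.planted):
            raise ValidationError("n_probes must cover all planted probes")
        if self.sigma_bg <= 0:
            raise ValidationError("sigma_bg must be positive")
        n_a = sum(1 for p in self.planted if p.role == "pair_A")
        n_b = sum(1 for p in self.planted if p.role == "pair_B")
        if n_a != n_b:
            raise ValidationError("pair_A and pair_B roles must come in pairs")

    def to_dict(self) -> dict:
        return {
            "n_tumor": self.n_tumor,
            "n_normal": self.n_normal,
            "n_probes": self.n_probes,
            "planted": [
                {"role": p.role, "effect": p.effect, "coverage": p.coverage}
                for p in self.planted
            ],
            "mu_bg": self.mu_bg,
            "sigma_bg": self.sigma_bg,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SyntheticSpec":
        planted = tuple(
            PlantedProbe(
                role=p["role"],
                effect=float(p["effect"]),
                coverage=float(p.get("coverage", 0.9)),
            )
            for p in payload.get("planted", [])
        )
        return cls(
            n_tumor=int(payload.get("n_tumor", 30)),
            n_normal=int(payload.get("n_normal", 30)),
            n_probes=int(payload.get("n_probes", 500)),
            planted=planted,
            mu_bg=float(payload.get("mu_bg", 8.0)),
            sigma_bg=float(payload.get("sigma_bg", 1.0)),
            seed=int(payload.get("seed", 0)),
        )


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, dict]:
    """Draw a dataset and its ground truth from the spec.

    Background probes are iid Normal(mu_bg, sigma_bg) in both classes.
    Planted probes occupy the first rows, in spec order. Tumor samples come
    first in column order (``T001``...), then normals (``N001``...). The
    truth dict records, per planted probe, its id, role, effect and the tumor
    sample ids that received the shift.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_tumor + spec.n_normal
    values = rng.normal(spec.mu_bg, spec.sigma_bg, size=(spec.n_probes, n))

    width = max(3, len(str(max(spec.n_tumor, spec.n_normal))))
    sample_ids = [f"T{i + 1:0{width}d}" for i in range(spec.n_tumor)] + [
        f"N{i + 1:0{width}d}" for i in range(spec.n_normal)
    ]
    labels = ["tumor"] * spec.n_tumor + ["normal"] * spec.n_normal
    pwidth = max(4, len(str(spec.n_probes)))
    probe_ids = [f"P{i + 1:0{pwidth}d}" for i in range(spec.n_probes)]

    tumor_cols = np.arange(spec.n_tumor)
    truth_planted: list[dict] = []
    pending_pair_subset: list[np.ndarray] = []  # FIFO pairing of A with B
    for row, planted in enumerate(spec.planted):
        delta = planted.effect * spec.sigma_bg
        if planted.role == "single_marker":
            cols = tumor_cols
            values[row, cols] += delta
        elif planted.role == "down_marker":
            cols = tumor_cols
            values[row, cols] -= delta
        elif planted.role == "pair_A":
            size = int(round(planted.coverage * spec.n_tumor))
            size = min(max(size, 1), spec.n_tumor - 1)
            cols = np.sort(rng.choice(spec.n_tumor, size=size, replace=False))
            pending_pair_subset.append(cols)
            values[row, cols] += delta
        else:  # pair_B: complement of the matching pair_A subset
            a_cols = pending_pair_subset.pop(0)
            cols = np.setdiff1d(tumor_cols, a_cols)
            values[row, cols] += delta
        truth_planted.append(
            {
                "probe_id": probe_ids[row],
                "role": planted.role,
                "effect": planted.effect,
                "shifted_samples": [sample_ids[c] for c in cols],
            }
        )

    ds = ExpressionDataset(
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        labels=labels,
        values=values,
        meta={"source": "synthetic", "spec": spec.to_dict()},
    )
    truth = {"spec": spec.to_dict(), "planted": truth_planted}
    return ds, truth


def pair_scenario(
    seed: int,
    n_tumor: int = 30,
    n_normal: int = 30,
    n_probes: int = 500,
    effect: float = 2.0,
    coverage: float = 0.9,
) -> SyntheticSpec:
    """Canonical complementary-pair study conditions.

    Gene A separates ``coverage`` of the tumors, gene B exactly the rest;
    the remaining probes are background noise.
    """
    return SyntheticSpec(
        n_tumor=n_tumor,
        n_normal=n_normal,
        n_probes=n_probes,
        planted=(
            PlantedProbe("pair_A", effect, coverage),
            PlantedProbe("pair_B", effect, coverage),
        ),
        seed=seed,
    )


def single_marker_scenario(
    seed: int,
    n_tumor: int = 30,
    n_normal: int = 30,
    n_probes: int = 500,
    effect: float = 5.0,
) -> SyntheticSpec:
    """One strongly overexpressed marker among background noise."""
    return SyntheticSpec(
        n_tumor=n_tumor,
        n_normal=n_normal,
        n_probes=n_probes,
        planted=(PlantedProbe("single_marker", effect),),
        seed=seed,
    )


def null_scenario(
    seed: int, n_tumor: int = 20, n_normal: int = 20, n_probes: int = 500
) -> SyntheticSpec:
    """Pure background noise: no planted probes at all."""
    return SyntheticSpec(
        n_tumor=n_tumor, n_normal=n_normal, n_probes=n_probes, seed=seed
    )
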