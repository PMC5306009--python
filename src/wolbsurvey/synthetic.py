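"""Synthetic screening databases with known ground truth.

The generator draws data exactly from the generative reading of the model:
per-species prevalence ~ Beta(pbar*theta, (1-pbar)*theta) with
logit(pbar) = alpha_true + beta_true * habitat, then infected counts
~ Binomial(n_tested, prevalence). On top of that clean base it can emulate
the two survey biases real databases carry:

* *targeted repeat sampling* — extra records for some species, optionally
  chosen with probability proportional to their true prevalence (studies
  revisiting species already known to be infected), which inflates
  full-database estimates relative to the one-record-per-species reduction;
* *family over-representation* — extra species of one family (mosquitoes
  being the canonical case) with an optional logit-scale prevalence shift.

Every run returns the table together with a :class:`SyntheticTruth` record
holding the generating parameters, per-species prevalences and the implied
true incidence per group, so recovery tests know exactly what to aim for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .incidence import DEFAULT_THRESHOLD, incidence_above_threshold
from .model import beta_shapes, logistic
from .survey import SurveyTable

#: Tested-per-species counts shaped like real screening surveys: most species
#: are screened with a handful of individuals, a few with hundreds.
DEFAULT_TESTED_COUNTS = (
    [1] * 24 + [2] * 14 + [3] * 10 + [4] * 8 + [5] * 7 + [6] * 5 + [7] * 4
    + [8] * 4 + [9] * 3 + [10] * 3 + [12, 14, 16, 18, 20, 24, 28, 32, 40, 48]
    + [60, 80, 100, 150, 250]
)


@dataclass(frozen=True)
class RepeatSpec:
    """Targeted repeat sampling: ``fraction`` of species get one extra record;
    with ``bias`` on, species are picked proportionally to true prevalence."""

    fraction: float = 0.5
    bias: bool = True

    def __post_init__(self):
        if not 0 <= self.fraction <= 1:
            raise ValueError("repeat fraction must lie in [0, 1]")


@dataclass(frozen=True)
class FamilySpec:
    """Over-represented family: extra aquatic species of ``family`` in
    ``order`` until the family makes up ``share`` of aquatic records;
    ``logit_shift`` raises (or lowers) their mean prevalence."""

    family: str = "Culicidae"
    order: str = "Diptera"
    share: float = 0.28
    logit_shift: float = 0.0

    def __post_init__(self):
        if not 0 <= self.share < 1:
            raise ValueError("family share must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters of a generated survey (the recovery target)."""

    n_species_aquatic: int = 500
    n_species_terrestrial: int = 500
    alpha_true: float = 0.0
    beta_true: float = 0.5
    theta_true: float = 1.5
    tested_per_species: int | list | tuple | str = "empirical"
    repeat_sampling: RepeatSpec | None = None
    overrepresented_family: FamilySpec | None = None
    seed: int = 0

    def __post_init__(self):
        if self.theta_true <= 0:
            raise ValueError("theta_true must be > 0")
        if self.n_species_aquatic + self.n_species_terrestrial < 1:
            raise ValueError("need at least one species")


@dataclass
class SyntheticTruth:
    """Everything the generator knew: parameters, per-species prevalences and
    implied true incidence per group."""

    alpha_true: float
    beta_true: float
    theta_true: float
    threshold: float
    p_bar: dict[str, float]
    incidence: dict[str, float]
    prevalence: dict[str, float] = field(default_factory=dict)  # species -> p
    seed: int = 0

    def to_sidecar(self, path: str | Path) -> None:
        """Write scalar truth as a plain-text key=value sidecar."""
        lines = [
            f"alpha_true={self.alpha_true!r}",
            f"beta_true={self.beta_true!r}",
            f"theta_true={self.theta_true!r}",
            f"threshold={self.threshold!r}",
            f"seed={self.seed}",
        ]
        for g in sorted(self.p_bar):
            lines.append(f"p_bar_{g}={self.p_bar[g]!r}")
        for g in sorted(self.incidence):
            lines.append(f"incidence_{g}={self.incidence[g]!r}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_sidecar(cls, path: str | Path) -> "SyntheticTruth":
        kv: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if line.strip() and not line.startswith("#"):
                k, _, v = line.partition("=")
                kv[k.strip()] = v.strip()
        p_bar = {k[len("p_bar_"):]: float(v) for k, v in kv.items()
                 if k.startswith("p_bar_")}
        incidence = {k[len("incidence_"):]: float(v) for k, v in kv.items()
                     if k.startswith("incidence_")}
        return cls(
            alpha_true=float(kv["alpha_true"]),
            beta_true=float(kv["beta_true"]),
            theta_true=float(kv["theta_true"]),
            threshold=float(kv["threshold"]),
            p_bar=p_bar,
            incidence=incidence,
            seed=int(kv["seed"]),
        )


_ORDERS_AQ = ["Diptera", "Ephemeroptera", "Trichoptera", "Plecoptera",
              "Odonata", "Coleoptera", "Hemiptera"]
_ORDERS_TERR = ["Lepidoptera", "Hymenoptera", "Coleoptera", "Hemiptera",
                "Orthoptera", "Diptera"]


def _draw_tested(spec: SyntheticSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    t = spec.tested_per_species
    if isinstance(t, str):
        if t != "empirical":
            raise ValueError(f"unknown tested_per_species spec {t!r}")
        pool = np.asarray(DEFAULT_TESTED_COUNTS)
        return rng.choice(pool, size=size, replace=True)
    if isinstance(t, (int, np.integer)):
        return np.full(size, int(t))
    pool = np.asarray(list(t), dtype=int)
    return rng.choice(pool, size=size, replace=True)


def generate_survey(spec: SyntheticSpec) -> tuple[SurveyTable, SyntheticTruth]:
    """Generate one synthetic screening database plus its truth record.

    Deterministic under a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    rows: list[dict] = []
    prevalence: dict[str, float] = {}
    theta = spec.theta_true

    groups = [("aquatic", spec.n_species_aquatic, 0.0, _ORDERS_AQ),
              ("terrestrial", spec.n_species_terrestrial, 1.0, _ORDERS_TERR)]
    p_bar_by_group: dict[str, float] = {}
    for habitat, n_species, x, orders in groups:
        p_bar = float(logistic(spec.alpha_true + spec.beta_true * x))
        p_bar_by_group[habitat] = p_bar
        if n_species == 0:
            continue
        a, b = beta_shapes(p_bar, theta)
        prev = rng.beta(a, b, size=n_species)
        n_tested = _draw_tested(spec, n_species, rng)
        infected = rng.binomial(n_tested, prev)
        order_labels = rng.choice(orders, size=n_species, replace=True)
        for i in range(n_species):
            sp = f"{habitat[:2]}_sp{i:05d}"
            prevalence[sp] = float(prev[i])
            rows.append(dict(
                species_id=sp, order=str(order_labels[i]), family="",
                habitat=habitat, n_tested=int(n_tested[i]),
                n_infected=int(infected[i]), source="synthetic",
            ))

    if spec.overrepresented_family is not None:
        fam = spec.overrepresented_family
        n_aq = sum(1 for r in rows if r["habitat"] == "aquatic")
        # extra species so the family reaches `share` of aquatic records
        n_extra = int(round(fam.share / (1.0 - fam.share) * n_aq))
        if n_extra > 0:
            p_fam = float(logistic(spec.alpha_true + fam.logit_shift))
            a, b = beta_shapes(p_fam, theta)
            prev = rng.beta(a, b, size=n_extra)
            n_tested = _draw_tested(spec, n_extra, rng)
            infected = rng.binomial(n_tested, prev)
            for i in range(n_extra):
                sp = f"{fam.family.lower()}_sp{i:05d}"
                prevalence[sp] = float(prev[i])
                rows.append(dict(
                    species_id=sp, order=fam.order, family=fam.family,
                    habitat="aquatic", n_tested=int(n_tested[i]),
                    n_infected=int(infected[i]), source="synthetic",
                ))

    table = SurveyTable(pd.DataFrame(rows), metadata={"synthetic": True,
                                                      "seed": spec.seed})
    truth = SyntheticTruth(
        alpha_true=spec.alpha_true, beta_true=spec.beta_true,
        theta_true=spec.theta_true, threshold=DEFAULT_THRESHOLD,
        p_bar=p_bar_by_group,
        incidence={g: float(incidence_above_threshold(p, theta))
                   for g, p in p_bar_by_group.items()},
        prevalence=prevalence, seed=spec.seed,
    )

    if spec.repeat_sampling is not None:
        table = inject_targeted_repeats(table, truth,
                                        spec.repeat_sampling.fraction,
                                        spec.repeat_sampling.bias,
                                        seed=spec.seed + 1)
    return table, truth


def inject_targeted_repeats(table: SurveyTable, truth: SyntheticTruth,
                            fraction: float, bias_flag: bool,
                            seed: int) -> SurveyTable:
    """Append duplicate-species records emulating targeted resampling.

    ``fraction`` of the species receive one extra record each; with
    ``bias_flag`` the species are chosen with probability proportional to
    their true prevalence (studies going back to hosts known to be infected).
    The extra record's count is resampled from the table's own n_tested pool
    and its positives drawn from the species' true prevalence.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0 or len(table) == 0:
        return SurveyTable(table.frame, dict(table.metadata))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    df = table.frame
    species = df.drop_duplicates("species_id")
    n_extra = int(round(fraction * len(species)))
    if n_extra == 0:
        return SurveyTable(df, dict(table.metadata))
    prev = np.array([truth.prevalence[s] for s in species["species_id"]])
    if bias_flag:
        weights = prev + 1e-9
        weights = weights / weights.sum()
    else:
        weights = np.full(len(species), 1.0 / len(species))
    picked = rng.choice(len(species), size=n_extra, replace=False,
                        p=weights) if n_extra < len(species) else np.arange(len(species))
    pool = df["n_tested"].to_numpy()
    new_rows = []
    for idx in picked:
        row = species.iloc[idx]
        n_t = int(rng.choice(pool))
        p = truth.prevalence[row["species_id"]]
        new_rows.append(dict(
            species_id=row["species_id"], order=row["order"],
            family=row["family"], habitat=row["habitat"], n_tested=n_t,
            n_infected=int(rng.binomial(n_t, p)), source="synthetic-repeat",
        ))
    out = pd.concat([df, pd.DataFrame(new_rows)], ignore_index=True)
    meta = dict(table.metadata, repeats_injected=n_extra, repeat_bias=bias_flag)
    return SurveyTable(out, meta)
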