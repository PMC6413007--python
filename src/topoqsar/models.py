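"""Linear QSAR models, the discriminant applicability window, and the
screening cascade.

The two packaged models target the formylpeptide receptor (FPR) library:

* ``fpr_discriminant`` — the linear discriminant score
  DF = 245.5 - 296.2*Cchi1p + 50.2*Dchi4pc - 0.0034*W + 4.4*V4,
  with applicability window (-8, 8): a molecule is predicted active when
  0 < DF < 8, inactive when -8 <= DF <= 0, and unclassified outside [-8, 8).
* ``fpr_affinity`` — the regression
  Log k_i = 76.50 + 0.000033*ww - 9.50*MAXDN - 15.68*BELm5 - 3.18*GGI10
  - 5.12*VEA1, predicting the decimal log of the binding-affinity constant
  (nM scale); Log k_i < 2.60 corresponds to binding below 400 nM and
  Log k_i < 1.0 to below 10 nM.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .conventions import Conventions
from .descriptors import DescriptorCalculator

ACTIVE, INACTIVE, UNCLASSIFIED = "active", "inactive", "unclassified"

#: activity tiers on the predicted Log k_i
LOGKI_ACTIVE_CUT = 2.60   # 400 nM
LOGKI_HIGH_CUT = 1.0      # 10 nM


class MissingDescriptorError(KeyError):
    """A model term has no defined descriptor value for a molecule."""


@dataclass(frozen=True)
class LinearQsarModel:
    """Intercept + named linear terms, with an optional applicability window
    on the model output."""

    name: str
    intercept: float
    terms: dict[str, float]
    response: str = ""
    domain_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.domain_window is not None and not self.domain_window[0] < self.domain_window[1]:
            raise ValueError("domain window must satisfy low < high")

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.terms)

    def predict(self, descriptors: dict[str, float]) -> float:
        """Evaluate the model on one descriptor map."""
        total = self.intercept
        for term, coeff in self.terms.items():
            if term not in descriptors:
                raise MissingDescriptorError(f"model {self.name!r}: missing term {term!r}")
            val = descriptors[term]
            if val is None or (isinstance(val, float) and math.isnan(val)):
                raise MissingDescriptorError(f"model {self.name!r}: term {term!r} undefined")
            total += coeff * val
        return total

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "intercept": self.intercept,
                "terms": self.terms,
                "response": self.response,
                "domain_window": self.domain_window,
            },
            indent=2,
        )


def load_model(path) -> LinearQsarModel:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    window = data.get("domain_window")
    return LinearQsarModel(
        name=data["name"],
        intercept=float(data["intercept"]),
        terms={k: float(v) for k, v in data["terms"].items()},
        response=data.get("response", ""),
        domain_window=tuple(window) if window else None,
    )


def packaged_model_path(name: str) -> Path:
    return Path(__file__).parent / "data" / "models" / f"{name}.json"


def load_packaged_models() -> tuple[LinearQsarModel, LinearQsarModel]:
    """The packaged (discriminant, affinity-regression) model pair."""
    return (
        load_model(packaged_model_path("fpr_discriminant")),
        load_model(packaged_model_path("fpr_affinity")),
    )


def classify(df_value: float, window: tuple[float, float] = (-8.0, 8.0)) -> str:
    """Three-way classification of a discriminant score.

    Active strictly inside (0, high); inactive in [low, 0] (a score of
    exactly 0 is inactive); unclassified when DF >= high or DF < low
    (outside the applicability domain).
    """
    low, high = window
    if 0.0 < df_value < high:
        return ACTIVE
    if low <= df_value <= 0.0:
        return INACTIVE
    return UNCLASSIFIED


def prob_active(df_value: float) -> float:
    """Model-posterior (convention): logistic transform of the discriminant
    score, prior log-odds already absorbed in the intercept."""
    return 1.0 / (1.0 + math.exp(-df_value))


def activity_tier(logki: float) -> str:
    if logki < LOGKI_HIGH_CUT:
        return "high"
    if logki < LOGKI_ACTIVE_CUT:
        return "moderate"
    return "none"


@dataclass
class ScreenRecord:
    id_code: str
    smiles: str
    df: float
    prob_a: float
    label: str
    logki: float | None = None    # only for DF-actives
    tier: str | None = None


@dataclass
class ScreenSummary:
    n_total: int = 0
    n_active: int = 0
    n_logki_lt_260: int = 0
    n_logki_lt_10: int = 0
    n_rejected: int = 0


@dataclass
class ScreenResult:
    records: list[ScreenRecord] = field(default_factory=list)
    rejects: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    summary: ScreenSummary = field(default_factory=ScreenSummary)
    conventions: dict[str, str] = field(default_factory=dict)


def screen_library(
    mols,
    model_df: LinearQsarModel,
    model_logki: LinearQsarModel,
    conventions: Conventions | None = None,
    thresholds: tuple[float, float] = (LOGKI_ACTIVE_CUT, LOGKI_HIGH_CUT),
) -> ScreenResult:
    """Run the two-stage screening cascade.

    Stage 1 evaluates the discriminant on every molecule and classifies it by
    the applicability window.  Stage 2 predicts Log k_i *only* for the
    DF-actives and tiers them by the (strict) thresholds.  Molecules whose
    descriptors fail to compute are collected in the rejects report, not
    raised.

    ``mols`` yields objects with ``id_code``, ``smiles`` and ``graph()``
    (e.g. :class:`~topoqsar.library.EnumeratedMolecule`).
    """
    conv = conventions or Conventions()
    cut_active, cut_high = thresholds
    res = ScreenResult(conventions=conv.describe())
    window = model_df.domain_window or (-8.0, 8.0)
    for m in mols:
        res.summary.n_total += 1
        try:
            calc = DescriptorCalculator(m.graph(), conventions=conv)
            df = model_df.predict(calc.compute(model_df.descriptor_names))
            label = classify(df, window)
            rec = ScreenRecord(
                id_code=m.id_code, smiles=m.smiles, df=df,
                prob_a=prob_active(df), label=label,
            )
            if label == ACTIVE:
                res.summary.n_active += 1
                logki = model_logki.predict(calc.compute(model_logki.descriptor_names))
                rec.logki = logki
                rec.tier = activity_tier(logki)
                if logki < cut_active:
                    res.summary.n_logki_lt_260 += 1
                if logki < cut_high:
                    res.summary.n_logki_lt_10 += 1
            res.records.append(rec)
        except Exception as exc:  # noqa: BLE001 - per-molecule fault isolation
            res.rejects.append((m.id_code, str(exc)))
            res.summary.n_rejected += 1
    return res
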