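"""Stage 2 scoring: relation scorers over anonymized instances.

A relation scorer maps a labelled sentence to a prediction v_s in [0, 1].
Three implementations live here:

* :class:`RuleRelationScorer` — deterministic trigger-based stub used by
  the hermetic test surface.  Its asymmetric scores (agent-before-target
  scores high, reversed order lower) make direction observable end to
  end.
* :class:`NoisyScorer` — wraps any scorer with bounded uniform noise, for
  robustness experiments.
* :func:`finetune_adapter` — optional transformer fine-tuning behind a
  capability check; the package installs and tests without deep-learning
  dependencies.
"""

from __future__ import annotations

import hashlib
import importlib.util
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np

from .preprocess import TRIGGER_STEMS
from .types import AGENT_TAG, TARGET_TAG, RelationInstance, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "RelationScorer",
    "ScorerRules",
    "RuleRelationScorer",
    "NoisyScorer",
    "TrainConfig",
    "CapabilityError",
    "stub_score",
    "score_instances",
    "classify",
    "finetune_adapter",
]


class RelationScorer(Protocol):
    """Contract: labelled text -> v in [0, 1], plus identifying metadata."""

    name: str

    def score(self, labelled_text: str) -> float: ...


@dataclass(frozen=True)
class ScorerRules:
    """Configuration of the rule stub.

    ``directed`` is returned when a trigger occurs between or adjacent to
    the tag pair with the agent tag first; ``reversed`` when the target
    tag precedes the agent tag; ``none`` when no trigger is near the
    pair.  ``window`` is the adjacency margin in characters around the
    tag span.
    """

    triggers: tuple[str, ...] = TRIGGER_STEMS
    directed: float = 0.9
    reversed: float = 0.6
    none: float = 0.1
    window: int = 40


def stub_score(instance: RelationInstance, rules: ScorerRules = ScorerRules()) -> float:
    """Deterministic rule score for one anonymized instance."""
    text = instance.labelled_text
    a = text.find(AGENT_TAG)
    t = text.find(TARGET_TAG)
    if a < 0 or t < 0:
        raise ValidationError(
            f"{instance.instance_id}: labelled text must contain both tags"
        )
    lo = max(0, min(a, t) - rules.window)
    hi = min(len(text), max(a + len(AGENT_TAG), t + len(TARGET_TAG)) + rules.window)
    region = text[lo:hi].casefold()
    if any(trig in region for trig in rules.triggers):
        return rules.directed if a < t else rules.reversed
    return rules.none


@dataclass(frozen=True)
class RuleRelationScorer:
    """Trigger-rule scorer satisfying the :class:`RelationScorer` contract."""

    rules: ScorerRules = ScorerRules()
    name: str = "rule-stub"

    def score(self, labelled_text: str) -> float:
        dummy = RelationInstance(
            instance_id="adhoc",
            sentence_id="adhoc",
            agent="a",
            target="t",
            labelled_text=labelled_text,
        )
        return stub_score(dummy, self.rules)

    @property
    def config_digest(self) -> str:
        blob = json.dumps(
            {
                "triggers": self.rules.triggers,
                "directed": self.rules.directed,
                "reversed": self.rules.reversed,
                "none": self.rules.none,
                "window": self.rules.window,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class NoisyScorer:
    """Adds bounded uniform noise (clipped to [0, 1]) to a base scorer."""

    base: RelationScorer
    epsilon: float = 0.2
    seed: int = 0
    name: str = "noisy"

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed)

    def score(self, labelled_text: str) -> float:
        v = self.base.score(labelled_text)
        v += self._rng.uniform(-self.epsilon, self.epsilon)
        return float(min(1.0, max(0.0, v)))


def score_instances(
    instances: Sequence[RelationInstance], scorer: RelationScorer
) -> list[RelationInstance]:
    """Score every instance, preserving input order.

    A scorer failure on one instance leaves its score absent (logged) and
    the run continues; :func:`classify` will then reject the batch rather
    than silently drop it.
    """
    scored = []
    for inst in instances:
        try:
            v = float(scorer.score(inst.labelled_text))
        except Exception as exc:
            logger.warning("scorer failed on %s: %s", inst.instance_id, exc)
            scored.append(inst.with_score(None))
            continue
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"scorer returned {v} outside [0, 1]")
        scored.append(inst.with_score(v))
    return scored


def classify(
    scored: Sequence[RelationInstance], cutoff: float = 0.5
) -> list[RelationInstance]:
    """Positive instances: score >= cutoff.  Monotone in ``cutoff``."""
    if not (0.0 <= cutoff <= 1.0):
        raise ValidationError("cutoff must be in [0, 1]")
    for inst in scored:
        if inst.score is None:
            raise ValidationError(f"{inst.instance_id} is unscored")
    return [inst for inst in scored if inst.score >= cutoff]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for transformer fine-tuning.

    Defaults: biomedical BERT base, token length 256 (512 for corpora
    with long sentences), BertAdam, batch 8, 10 or 20 epochs depending on
    dataset size, learning rate 2e-5, warmup 0.1, weight decay 0.01.
    """

    base_model: str = "biobert_v1.1_pubmed"
    max_token_length: int = 256
    optimizer: str = "BertAdam"
    batch_size: int = 8
    epochs: int = 10
    learning_rate: float = 2e-5
    warmup_proportion: float = 0.1
    weight_decay: float = 0.01

    def __post_init__(self) -> None:
        for name in ("max_token_length", "batch_size", "epochs", "learning_rate",
                     "warmup_proportion", "weight_decay"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @property
    def digest(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in (
                "base_model", "max_token_length", "optimizer", "batch_size",
                "epochs", "learning_rate", "warmup_proportion", "weight_decay")},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class CapabilityError(RuntimeError):
    """An optional capability's dependencies are not installed."""


def finetune_adapter(
    train: Sequence[RelationInstance], config: TrainConfig = TrainConfig()
) -> RelationScorer:
    """Fine-tune a transformer relation classifier (optional capability).

    Requires ``torch`` and ``transformers``; raises
    :class:`CapabilityError` when they are absent rather than silently
    falling back to another scorer.  The returned object honors the
    :class:`RelationScorer` contract.
    """
    if not train:
        raise ValidationError("training dataset must be non-empty")
    for inst in train:
        if inst.label is None:
            raise ValidationError(f"{inst.instance_id}: missing gold label")
    for dep in ("torch", "transformers"):
        if importlib.util.find_spec(dep) is None:
            raise CapabilityError(
                f"fine-tuning requires the optional dependency {dep!r}; "
                "install it or use the rule scorer"
            )
    from ._finetune import train_transformer_scorer  # pragma: no cover

    return train_transformer_scorer(train, config)  # pragma: no cover
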