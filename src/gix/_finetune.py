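"""Transformer fine-tuning loop (optional; requires torch + transformers).

Imported lazily by :func:`gix.relation_classifier.finetune_adapter` only
after its dependency check has passed.
"""

from __future__ import annotations

from typing import Sequence

from .relation_classifier import RelationScorer, TrainConfig
from .types import RelationInstance


def train_transformer_scorer(
    train: Sequence[RelationInstance], config: TrainConfig
) -> RelationScorer:
    import torch
    from torch.utils.data import DataLoader
    from transformers import (
        AutoModelForSequenceClassification,
        AutoTokenizer,
        get_linear_schedule_with_warmup,
    )

    tokenizer = AutoTokenizer.from_pretrained(config.base_model)
    model = AutoModelForSequenceClassification.from_pretrained(
        config.base_model, num_labels=2
    )

    def encode(batch):
        texts, labels = zip(*batch)
        enc = tokenizer(
            list(texts),
            truncation=True,
            max_length=config.max_token_length,
            padding=True,
            return_tensors="pt",
        )
        enc["labels"] = torch.tensor(labels)
        return enc

    data = [(inst.labelled_text, int(inst.label)) for inst in train]
    loader = DataLoader(data, batch_size=config.batch_size, shuffle=True, collate_fn=encode)

    optimizer = torch.optim.AdamW(
        model.parameters(), lr=config.learning_rate, weight_decay=config.weight_decay
    )
    total_steps = len(loader) * config.epochs
    scheduler = get_linear_schedule_with_warmup(
        optimizer,
        num_warmup_steps=int(config.warmup_proportion * total_steps),
        num_training_steps=total_steps,
    )

    model.train()
    for _ in range(config.epochs):
        for batch in loader:
            optimizer.zero_grad()
            out = model(**batch)
            out.loss.backward()
            optimizer.step()
            scheduler.step()

    model.eval()

    class _TransformerScorer:
        name = f"transformer:{config.digest}"

        def score(self, labelled_text: str) -> float:
            enc = tokenizer(
                labelled_text,
                truncation=True,
                max_length=config.max_token_length,
                return_tensors="pt",
            )
            with torch.no_grad():
                logits = model(**enc).logits
            return float(torch.softmax(logits, dim=-1)[0, 1])

    return _TransformerScorer()
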