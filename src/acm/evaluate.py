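"""Evaluation harness: sub-family CMs vs. cherry picking vs. one aCM.

For a multi-sub-family alignment the harness builds

* one classical model per consensus structure trained on *all* rows
  (``all+<subfamily>``),
* one classical model per sub-family trained on its own rows only
  (``only+<subfamily>``), and
* the ambivalent model from everything (``acm``),

then scores every ungapped alignment row (positives) and one dinucleotide
shuffle per row (negatives) against every model.  Summaries report medians
and quartiles per model and sequence group, the *cherry-picking* median
(per-sequence best over the ``only+`` sub-models, then the median) and the
*discriminatory power* (median of positives minus median of negatives).
Medians interpolate linearly for even counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AnnotatedAlignment, ModelFile
from .search import cyk_align, dinucleotide_shuffle
from .training import BuildConfig, build_model

__all__ = ["EvalSummary", "run_comparison", "summarize"]


@dataclass
class EvalSummary:
    """Bit scores of every (model, query) pair plus aggregation helpers."""

    scores: pd.DataFrame  # columns: model, query, group, label, bit_score
    build_errors: dict[str, str] = field(default_factory=dict)

    def median(
        self,
        model: str,
        group: str | None = None,
        label: str = "positive",
    ) -> float:
        df = self.scores
        sel = (df["model"] == model) & (df["label"] == label)
        if group is not None:
            sel &= df["group"] == group
        vals = df.loc[sel, "bit_score"]
        if vals.empty:
            raise KeyError(f"no scores for model={model!r} group={group!r}")
        return float(np.median(vals))

    def quartiles(
        self, model: str, group: str | None = None, label: str = "positive"
    ) -> tuple[float, float, float]:
        df = self.scores
        sel = (df["model"] == model) & (df["label"] == label)
        if group is not None:
            sel &= df["group"] == group
        vals = df.loc[sel, "bit_score"].to_numpy()
        q1, q2, q3 = np.percentile(vals, [25, 50, 75])
        return float(q1), float(q2), float(q3)

    def discriminatory_power(self, model: str) -> float:
        return self.median(model, label="positive") - self.median(
            model, label="negative"
        )

    def cherry_pick_median(
        self, models: list[str], group: str | None = None, label: str = "positive"
    ) -> float:
        """Median over per-sequence maxima across the given models."""
        df = self.scores
        sel = df["model"].isin(models) & (df["label"] == label)
        if group is not None:
            sel &= df["group"] == group
        best = df.loc[sel].groupby("query", sort=True)["bit_score"].max()
        if best.empty:
            raise KeyError("no scores to cherry-pick from")
        return float(np.median(best))

    def models(self) -> list[str]:
        return sorted(self.scores["model"].unique())

    def table(self) -> pd.DataFrame:
        """Median / quartile overview per model and sequence group."""
        records = []
        groups = [None] + sorted(self.scores["group"].unique())
        for model in self.models():
            for group in groups:
                for label in ("positive", "negative"):
                    df = self.scores
                    sel = (df["model"] == model) & (df["label"] == label)
                    if group is not None:
                        sel &= df["group"] == group
                    vals = df.loc[sel, "bit_score"].to_numpy()
                    if len(vals) == 0:
                        continue
                    q1, q2, q3 = np.percentile(vals, [25, 50, 75])
                    records.append(
                        {
                            "model": model,
                            "group": group or "all",
                            "label": label,
                            "n": len(vals),
                            "q1": q1,
                            "median": q2,
                            "q3": q3,
                        }
                    )
        return pd.DataFrame.from_records(records)


def summarize(
    results: list,
    grouping: dict[str, str] | None = None,
    model: str = "model",
) -> EvalSummary:
    """Aggregate a list of :class:`~acm.search.AlignmentResult` objects."""
    grouping = grouping or {}
    rows = [
        {
            "model": model,
            "query": r.query_name,
            "group": grouping.get(r.query_name, "all"),
            "label": r.label,
            "bit_score": r.bit_score,
        }
        for r in results
    ]
    return EvalSummary(pd.DataFrame.from_records(rows))


def _single_structure_view(
    alignment: AnnotatedAlignment, subfamily: str, rows: str
) -> AnnotatedAlignment:
    """Re-annotate the alignment with one consensus only.

    ``rows='all'`` keeps every row (the "all rows, structure i" models);
    ``rows='own'`` keeps the sub-family's rows only.
    """
    if rows == "all":
        kept = [(subfamily, n, s) for _f, n, s in alignment.rows]
    else:
        kept = [
            (subfamily, n, s)
            for f, n, s in alignment.rows
            if f == subfamily
        ]
    return AnnotatedAlignment(
        kept, {subfamily: alignment.structures[subfamily]}, alignment.n_columns
    )


def run_comparison(
    alignment: AnnotatedAlignment,
    seed: int,
    config: BuildConfig | None = None,
    mode: str = "glocal",
) -> EvalSummary:
    """Build all comparison models and score all rows plus shuffled negatives.

    Deterministic for a fixed seed: the shuffle stream is seeded per query
    index.  Build failures of individual models are recorded and the
    remaining models are still evaluated.
    """
    if len(alignment.subfamilies) < 2:
        raise ValueError("the comparison needs at least two sub-families")
    cfg = config or BuildConfig(seed=seed)

    builds: dict[str, AnnotatedAlignment] = {}
    for fam in alignment.subfamilies:
        builds[f"all+{fam}"] = _single_structure_view(alignment, fam, "all")
        builds[f"only+{fam}"] = _single_structure_view(alignment, fam, "own")
    builds["acm"] = alignment

    models: dict[str, ModelFile] = {}
    errors: dict[str, str] = {}
    for name, aln in builds.items():
        try:
            models[name] = build_model(aln, cfg)
        except Exception as exc:  # noqa: BLE001 - collected, not fatal
            errors[name] = str(exc)

    positives = alignment.ungapped()
    negatives = [
        (fam, f"{name}|shuffled", dinucleotide_shuffle(seq, seed=seed + i))
        for i, (fam, name, seq) in enumerate(positives)
    ]

    records = []
    for model_name, model in models.items():
        for label, triples in (("positive", positives), ("negative", negatives)):
            for fam, qname, seq in triples:
                res = cyk_align(model, seq, mode=mode)
                records.append(
                    {
                        "model": model_name,
                        "query": qname,
                        "group": fam,
                        "label": label,
                        "bit_score": res.bit_score,
                    }
                )
    return EvalSummary(pd.DataFrame.from_records(records), errors)
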