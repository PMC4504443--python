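"""Model / Results interface over the build-and-search pipeline.

:class:`AmbivalentCM` holds the family data (an annotated alignment) and the
construction settings; :meth:`AmbivalentCM.fit` runs the full construction
and training pipeline and returns an :class:`AmbivalentCMResults` carrying
the generated grammar, the trained parameters, build diagnostics and the
scoring methods.  The classical single-structure covariance model is the
n = 1 special case of the same pipeline.

Example
-------
>>> from acm import AmbivalentCM
>>> from acm.synthetic_fixtures import make_trna_like
>>> res = AmbivalentCM(make_trna_like(seed=7)).fit()
>>> hit = res.score("GGGGC" + "..." )          # doctest: +SKIP
>>> print(res.summary())                       # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .io_formats import (
    AnnotatedAlignment,
    ModelFile,
    read_model,
    read_stockholm,
    write_model,
)
from .search import (
    AlignmentResult,
    SearchSpaceCount,
    count_search_space,
    cyk_align,
    search_many,
)
from .training import BuildConfig, build_model

__all__ = ["AmbivalentCM", "AmbivalentCMResults"]


class AmbivalentCM:
    """An (ambivalent) covariance model specification prior to training."""

    def __init__(self, alignment: AnnotatedAlignment, **config):
        self.alignment = alignment
        self.config = BuildConfig(**config)

    @classmethod
    def from_stockholm(cls, path: str | Path, **config) -> "AmbivalentCM":
        return cls(read_stockholm(path), **config)

    @property
    def subfamilies(self) -> list[str]:
        return self.alignment.subfamilies

    def fit(self) -> "AmbivalentCMResults":
        return AmbivalentCMResults(build_model(self.alignment, self.config))


@dataclass
class AmbivalentCMResults:
    """A fitted family model: grammar, parameters and scoring methods."""

    model_file: ModelFile

    @property
    def grammar(self):
        return self.model_file.grammar

    @property
    def params(self):
        return self.model_file.params

    @property
    def provenance(self) -> dict:
        return self.model_file.provenance

    # --- scoring ---------------------------------------------------------

    def score(self, query: str, mode: str = "glocal") -> AlignmentResult:
        """CYK bit score of one RNA sequence against the fitted model."""
        return cyk_align(self.model_file, query, mode=mode)

    def score_many(
        self,
        records: list[tuple[str, str]],
        mode: str = "glocal",
        shuffle_seed: int | None = None,
    ) -> list[AlignmentResult]:
        return search_many(self.model_file, records, mode=mode, shuffle_seed=shuffle_seed)

    def search_space(self, query_length: int, mode: str = "glocal") -> SearchSpaceCount:
        return count_search_space(self.model_file, query_length, mode=mode)

    # --- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        write_model(self.model_file, path)

    @classmethod
    def load(cls, path: str | Path) -> "AmbivalentCMResults":
        return cls(read_model(path))

    # --- reporting --------------------------------------------------------

    def summary(self) -> str:
        g = self.grammar
        prov = self.provenance
        kinds: dict[str, int] = {}
        for node in g.nodes.values():
            kinds[node.kind] = kinds.get(node.kind, 0) + 1
        lines = [
            "Ambivalent covariance model",
            "===========================",
            f"sub-families:        {', '.join(g.subfamilies)}",
            f"alignment columns:   {g.n_columns}",
            f"grammar nodes:       {len(g.nodes)} "
            f"(pair {kinds.get('pair', 0)}, unpaired {kinds.get('open', 0)}, "
            f"skip {kinds.get('skip', 0)}, fork {kinds.get('fork', 0)})",
        ]
        if "k" in prov:
            lines.append(f"training sequences:  k={prov['k']}, k_eff={prov['k_eff']:.2f}")
        if "subfamily_sizes" in prov:
            sizes = ", ".join(f"{f}: {n}" for f, n in prov["subfamily_sizes"].items())
            lines.append(f"sub-family sizes:    {sizes}")
        forks = [i for i, n in g.nodes.items() if n.kind == "fork"]
        for idx in forks:
            node = g.nodes[idx]
            probs = []
            for m, child in enumerate(node.children):
                p = self.params.transition_prob(idx, f"branch_{m}")
                members = ",".join(g.nodes[child].members)
                probs.append(f"[{members}] p={p:.3f}")
            lines.append(f"fork {idx}:             " + "  ".join(probs))
        return "\n".join(lines)
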