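"""All-subsets model selection ranked by AICc with Akaike weights."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import SmoothBasis
from .gamm import FitError, FittedGAMM, GAMMSpec, fit

logger = logging.getLogger(__name__)


def aicc(log_lik: float, k: int, n: int) -> float:
    """AICc = -2 logLik + 2k + 2k(k+1)/(n - k - 1)."""
    if n <= k + 1:
        raise ValueError("finite-sample correction undefined for n <= k + 1")
    return -2.0 * log_lik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aiccs) -> np.ndarray:
    """exp(-delta/2) weights normalised over the candidate set."""
    a = np.asarray(aiccs, dtype=float)
    if a.size == 0 or not np.all(np.isfinite(a)):
        raise ValueError("need at least one finite AICc value")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class CandidateModel:
    terms: tuple
    fit: FittedGAMM | None
    df: int
    loglik: float
    aicc: float
    delta: float = np.nan
    weight: float = np.nan

    def includes(self, term: str) -> bool:
        return term in self.terms


@dataclass
class SelectionTable:
    """Candidates sorted ascending by AICc (the Table-1 analogue)."""

    candidates: list[CandidateModel]
    n: int
    all_terms: tuple = ()
    failures: list[tuple] = field(default_factory=list)

    @property
    def best(self) -> CandidateModel:
        return self.candidates[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            row = {t: ("+" if c.includes(t) else "") for t in self.all_terms}
            row.update(df=c.df, logLik=c.loglik, AICc=c.aicc,
                       delta=c.delta, weight=c.weight)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def dredge(table: pd.DataFrame, full_spec: GAMMSpec | None = None, *,
           keep_fits: bool = False, max_candidates: int = 1024) -> SelectionTable:
    """Fit every subset of the fixed terms and rank by AICc.

    Terms enter or leave whole (each smooth, and landform as one block);
    the nested random intercepts are retained in every candidate and all
    fits use maximum likelihood.  Candidates that fail to fit are logged,
    flagged and excluded from the weights.
    """
    full_spec = full_spec or GAMMSpec()
    all_terms = full_spec.fixed_terms
    n_cand = 2 ** len(all_terms)
    if n_cand > max_candidates:
        raise ValueError(f"{n_cand} candidates exceed max_candidates="
                         f"{max_candidates}")

    # smooth bases depend only on the covariate values: build once, share
    bases = {t: SmoothBasis(table[t].to_numpy(dtype=float), full_spec.k)
             for t in full_spec.smooth_terms}
    n = len(table)
    candidates, failures = [], []
    for subset in itertools.chain.from_iterable(
            itertools.combinations(all_terms, r)
            for r in range(len(all_terms) + 1)):
        spec = GAMMSpec(
            smooth_terms=tuple(t for t in subset if t != "landform"),
            landform="landform" in subset, random=full_spec.random,
            k=full_spec.k, response=full_spec.response,
            reference_level=full_spec.reference_level)
        try:
            m = fit(table, spec, bases={t: bases[t] for t in spec.smooth_terms})
        except FitError as exc:
            logger.warning("candidate %s failed: %s", spec.label(), exc)
            failures.append((subset, str(exc)))
            continue
        df = m.param_count()
        candidates.append(CandidateModel(
            terms=subset, fit=m if keep_fits else None, df=df,
            loglik=m.log_likelihood(), aicc=aicc(m.log_likelihood(), df, n)))

    if not candidates:
        raise FitError("no candidate model could be fitted")
    candidates.sort(key=lambda c: c.aicc)
    weights = akaike_weights([c.aicc for c in candidates])
    best = candidates[0].aicc
    for c, w in zip(candidates, weights):
        c.delta = c.aicc - best
        c.weight = float(w)
    return SelectionTable(candidates=candidates, n=n, all_terms=all_terms,
                          failures=failures)
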