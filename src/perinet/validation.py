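"""Simulation studies validating the estimators against known ground truth.

These are the package's built-in calibration checks: confidence-interval
coverage of the IRLS logistic fit on registries with planted effects,
agreement of the Louvain heuristic with the exhaustive modularity oracle on
small graphs, and planted-partition recovery of the community detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .association import Z975, fit_logistic
from .community import (
    DetectionParams,
    detect_communities,
    exhaustive_best_partition,
    louvain,
)
from .concordance import adjusted_rand
from .records import rurality_of_records
from .synthetic import (
    COVARIATE_MARGINALS,
    DEFAULT_COVARIATE_EFFECTS,
    GeneratorConfig,
    generate_registry,
    plant_partition_network,
)

#: Model used by the coverage study: every effect-bearing covariate, with
#: Unknown levels removed from the sampling marginals so all modeled levels
#: carry adequate event counts at rare-outcome sample sizes.
COVERAGE_MODEL_SPEC = (
    ("rurality", "urban"),
    ("preterm", "No"),
    ("plurality", "1"),
    ("tobacco", "No"),
    ("n_medical_risk_factors", "0"),
)


def _coverage_config(seed: int, n_deliveries: int) -> GeneratorConfig:
    clean_marginals = {
        cov: {lvl: w for lvl, w in levels.items() if lvl != "Unknown"}
        for cov, levels in COVARIATE_MARGINALS.items()
    }
    effects = {
        cov: {lvl: e for lvl, e in levels.items() if lvl != "Unknown"}
        for cov, levels in DEFAULT_COVARIATE_EFFECTS.items()
    }
    effects["payor"] = {}  # keep the fitted model saturated w.r.t. the truth
    return GeneratorConfig(
        seed=seed,
        n_deliveries=n_deliveries,
        p_unknown_county=0.0,
        covariate_marginals=clean_marginals,
        covariate_effects=effects,
    )


def coverage_truth() -> dict[str, float]:
    """True log-OR per fitted model term in the coverage study."""
    out: dict[str, float] = {}
    config = _coverage_config(0, 1)
    for cov, _ref in COVERAGE_MODEL_SPEC:
        for lvl, eff in config.covariate_effects.get(cov, {}).items():
            out[f"{cov}[{lvl}]"] = eff
    return out


@dataclass(frozen=True)
class CoverageResult:
    coverage: float          # pooled over terms and replicates
    per_term: dict[str, float]
    n_replicates: int
    n_converged: int


def ci_coverage_study(
    n_replicates: int = 200, n_deliveries: int = 100_000, seed: int = 0
) -> CoverageResult:
    """Wald 95% CI coverage of planted log-ORs across replicate registries.

    Each replicate generates a registry with known covariate effects, fits
    the transport model by IRLS, and records whether each term's interval
    covers its true value.
    """
    truth = coverage_truth()
    hits: dict[str, list[bool]] = {t: [] for t in truth}
    n_converged = 0
    for rep in range(n_replicates):
        config = _coverage_config(seed * 1000 + rep, n_deliveries)
        fac, cty, dlv, _ = generate_registry(config)
        dlv = dlv.copy()
        dlv["rurality"] = rurality_of_records(dlv, cty)
        fit = fit_logistic(dlv, COVERAGE_MODEL_SPEC, outcome="transported")
        n_converged += fit.converged
        for term, true in truth.items():
            b = fit.coefficients[term]
            s = fit.standard_errors[term]
            hits[term].append(abs(b - true) <= Z975 * s)
    per_term = {t: float(np.mean(h)) for t, h in hits.items()}
    pooled = float(np.mean([v for h in hits.values() for v in h]))
    return CoverageResult(
        coverage=pooled,
        per_term=per_term,
        n_replicates=n_replicates,
        n_converged=n_converged,
    )


@dataclass(frozen=True)
class OracleAgreement:
    n_graphs: int
    n_matched: int
    n_violations: int  # heuristic exceeding the global optimum (must be 0)

    @property
    def match_rate(self) -> float:
        return self.n_matched / self.n_graphs


def oracle_agreement_study(
    n_graphs: int = 100, max_nodes: int = 9, seed: int = 0
) -> OracleAgreement:
    """Louvain vs exhaustive optimum on random small weighted graphs."""
    rng = np.random.default_rng([seed, 101])
    n_done = matched = violations = 0
    while n_done < n_graphs:
        n = int(rng.integers(4, max_nodes + 1))
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
        if g.number_of_edges() == 0:
            continue
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.integers(1, 6))
        best = exhaustive_best_partition(g)
        heur = louvain(g, DetectionParams(seed=int(rng.integers(2**31))))
        n_done += 1
        if heur.modularity > best.modularity + 1e-9:
            violations += 1
        elif abs(heur.modularity - best.modularity) < 1e-9:
            matched += 1
    return OracleAgreement(n_graphs=n_done, n_matched=matched,
                           n_violations=violations)


def planted_recovery_study(
    n_seeds: int = 20,
    n_communities: int = 6,
    nodes_per_community: int = 12,
    p_in: float = 0.6,
    p_out: float = 0.02,
    seed: int = 0,
) -> float:
    """Mean adjusted Rand index of detected vs planted communities."""
    scores = []
    for s in range(n_seeds):
        net, planted = plant_partition_network(
            n_communities, nodes_per_community, p_in, p_out,
            seed=seed * 1000 + s,
        )
        detected = detect_communities(net, DetectionParams(seed=s))
        scores.append(adjusted_rand(detected, planted))
    return float(np.mean(scores))
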