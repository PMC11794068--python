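"""Seeded random model generator for property tests.

Generated models are valid linear models by construction: constants with
scores in [0, 10], auxiliaries whose plain references only point at earlier-
declared variables (so the algebra is acyclic and the constant-input
asymptote exists), delay times in ``[dt, 10*dt]``, and one stock integrating
one of the auxiliaries. The same seed always yields the same model.
"""

from __future__ import annotations

import numpy as np

from .core import ModelSpec, Term, VariableSpec

__all__ = ["generate_fixture_model"]


def generate_fixture_model(
    seed: int,
    n_constants: int = 4,
    n_auxiliaries: int = 6,
    n_delays: int = 2,
    dt: float = 1.0,
) -> ModelSpec:
    """Build a random valid model: ``n_constants`` score constants,
    ``n_auxiliaries`` linear auxiliaries (the requested number of delayed
    references distributed among them), and one stock."""
    if min(n_constants, n_auxiliaries, n_delays) < 0:
        raise ValueError("sizes must be non-negative")
    rng = np.random.default_rng(seed)
    variables: list[VariableSpec] = []
    for i in range(n_constants):
        variables.append(VariableSpec.constant(f"c{i}", round(float(rng.uniform(0, 10)), 6)))

    aux_rows: list[list[Term]] = []
    for i in range(n_auxiliaries):
        terms: list[Term] = [Term.lit(round(float(rng.uniform(0, 5)), 6))]
        pool = [v.name for v in variables]  # earlier-declared only: keeps algebra acyclic
        for name in rng.choice(pool, size=min(len(pool), int(rng.integers(1, 4))), replace=False):
            terms.append(Term.ref(str(name), round(float(rng.uniform(0.1, 2.0)), 6)))
        aux_rows.append(terms)
        variables.append(VariableSpec.auxiliary(f"a{i}", terms))

    # sprinkle delayed references over the auxiliaries (sources must be
    # declared before the consumer so the steady-state oracle stays acyclic)
    placed = 0
    guard = 0
    while placed < n_delays and n_auxiliaries > 0 and guard < 100 * max(1, n_delays):
        guard += 1
        i = int(rng.integers(0, n_auxiliaries))
        pool = [f"c{j}" for j in range(n_constants)] + [f"a{j}" for j in range(i)]
        if not pool:
            continue
        source = str(rng.choice(pool))
        delay_time = round(float(rng.uniform(dt, 10 * dt)), 6)
        new_terms = list(aux_rows[i]) + [
            Term.delay1(source, delay_time, round(float(rng.uniform(0.1, 2.0)), 6))
        ]
        aux_rows[i] = new_terms
        variables[n_constants + i] = VariableSpec.auxiliary(f"a{i}", new_terms)
        placed += 1

    if n_auxiliaries == 0:
        terms = [Term.lit(round(float(rng.uniform(0, 5)), 6))]
        if n_constants:
            terms.append(Term.ref("c0"))
        variables.append(VariableSpec.auxiliary("a0", terms))
        n_auxiliaries = 1
    inflow = f"a{int(rng.integers(0, n_auxiliaries))}"
    variables.append(VariableSpec.stock("s0", inflow, round(float(rng.uniform(0, 10)), 6)))
    return ModelSpec(variables=variables, metadata={"name": f"fixture-{seed}"})
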