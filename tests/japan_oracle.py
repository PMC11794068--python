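"""Engine-free oracle for the Japan pricing model.

The scoring table is transcribed literally as straight-line arithmetic and
advanced by hand — no kernel imports — so it can serve as an independent
reference for the simulation engine.
"""

from __future__ import annotations


def japan_recurrence(dt: float, n_steps: int, init: str = "default") -> dict[str, list[float]]:
    """Simulate the Japan model by hand; returns per-step series (length
    ``n_steps + 1``) for the five premiums, the flow and the stock.

    ``init`` is "default" (zero-start for delays no shorter than the step,
    equilibrium otherwise), "equilibrium" or "zero".
    """
    serious = 1.0
    nhs = 1.0
    safety = 1.0
    rct = 2.0
    other = 1.0
    favouring = 1.0
    becoming = 1.0
    faster = 1.0
    combination = 1.0
    reducing = 1.0
    easy = 1.0
    stable = 1.0
    new_mech = 2.0
    major = 2.0
    sig = 2.0
    japan = 2.0

    sak_eq = new_mech + sig + japan + major  # constant-input equilibrium = 8
    if init == "equilibrium":
        d_sig = sig
        d_rare = d_small = d_child = sak_eq
    elif init == "zero":
        d_sig = 0.0
        d_rare = d_small = d_child = 0.0
    elif init == "default":
        d_sig = 0.0 if 0.5 >= dt else sig
        d_rare = d_small = d_child = 0.0 if 5.0 >= dt else sak_eq
    else:
        raise ValueError(init)

    stock = 0.0
    out: dict[str, list[float]] = {
        "value premium": [], "marketability premium i": [], "marketability premium ii": [],
        "pediatrics premium": [], "sakigake premium": [], "flow": [], "stock": [],
    }
    for _ in range(n_steps + 1):
        action = 2 + new_mech
        target = 1 + new_mech
        validity = 2 + d_sig + combination
        no_std = 1 + serious
        rare = 5 + d_rare
        small = 5 + d_small
        child = 5 + d_child
        new_useful = nhs + action + target + serious
        effective = nhs + safety + validity + rct + other
        may_improve = nhs + becoming + favouring + no_std + combination + faster
        formulation = reducing + easy + stable + nhs
        value = formulation + may_improve + new_useful + effective
        sak = new_mech + sig + japan + major
        flow = 1.8 * value + 1.15 * rare + 1.05 * small + 1.125 * child + 1.15 * sak

        out["value premium"].append(value)
        out["marketability premium i"].append(rare)
        out["marketability premium ii"].append(small)
        out["pediatrics premium"].append(child)
        out["sakigake premium"].append(sak)
        out["flow"].append(flow)
        out["stock"].append(stock)

        d_sig = d_sig + (dt / 0.5) * (sig - d_sig)
        d_rare = d_rare + (dt / 5.0) * (sak - d_rare)
        d_small = d_small + (dt / 5.0) * (sak - d_small)
        d_child = d_child + (dt / 5.0) * (sak - d_child)
        stock = stock + dt * flow
    return out
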