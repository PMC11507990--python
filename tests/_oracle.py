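"""Independent brute-force oracle for small scheduling instances.

Everything here is recomputed from the problem statement (penalty formulas,
worst-case capacity check) without calling the package's optimization code,
so it can serve as the reference in equivalence tests.
"""

import itertools


def oracle_worst_case(pairs, gamma):
    """Worst-case block load: mean load plus the gamma largest deviations."""
    devs = sorted((h for _, h in pairs), reverse=True)
    return sum(t for t, _ in pairs) + sum(devs[: min(gamma, len(devs))])


def oracle_worst_case_enum(pairs, gamma):
    """Same quantity by explicit enumeration of all subsets of size <= gamma."""
    devs = [h for _, h in pairs]
    best = 0.0
    for k in range(0, min(gamma, len(devs)) + 1):
        for combo in itertools.combinations(devs, k):
            best = max(best, sum(combo))
    return sum(t for t, _ in pairs) + best


def oracle_optimum(instance, gamma=0, alpha=0.0):
    """Exhaustive search over all assignments; returns (objective, schedule).

    Feasibility of a candidate uses the worst-case load (deterministic when
    gamma == 0 or alpha == 0).  Intended for <= 8 patients and <= 3 blocks.
    """
    D = instance.horizon
    pats = instance.patients
    blocks = instance.blocks
    q = []
    p = []
    for pt in pats:
        w, l, u = pt.waited, pt.mwt, pt.urgency
        e = w + D + 1
        q.append((e + max(e - l, 0)) * u)
        p.append([(b.day + max(w + b.day - l, 0)) * u for b in blocks])

    best_obj, best_assign = None, None
    options = range(len(blocks) + 1)  # index len(blocks) == unscheduled
    for choice in itertools.product(options, repeat=len(pats)):
        loads = {j: [] for j in range(len(blocks))}
        obj = 0.0
        for i, c in enumerate(choice):
            if c == len(blocks):
                obj += q[i]
            else:
                obj += p[i][c]
                loads[c].append((pats[i].mean_duration, alpha * pats[i].sd_duration))
        feasible = all(
            oracle_worst_case(loads[j], gamma) <= blocks[j].capacity + 1e-9
            for j in range(len(blocks))
        )
        if feasible and (best_obj is None or obj < best_obj):
            best_obj, best_assign = obj, choice
    return best_obj, best_assign
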