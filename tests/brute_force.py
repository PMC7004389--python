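"""Independent brute-force re-implementation of the association scoring.

Used as the oracle in equivalence tests: it recomputes every update factor
directly from the printed formulas and chains probabilities through the
plain update rule p' = tau*p / ((tau-phi)*p + phi), with no log-odds
shortcuts and no shared code with the package's scoring engine.
"""

import math


def bf_ancestor_distances(parents, term):
    """Hop distance from term to each ancestor, by iterative relaxation."""
    dist = {term: 0}
    changed = True
    while changed:
        changed = False
        for node, d in list(dist.items()):
            for p in parents[node]:
                if p not in dist or d + 1 < dist[p]:
                    dist[p] = d + 1
                    changed = True
    dist.pop(term)
    return dist


def bf_alpha(r, b):
    if r > b:
        return (r - b) / (1.0 - b)
    if r < b:
        return (b - r) / b
    return 0.0


def bf_update(p, tau, phi):
    return tau * p / ((tau - phi) * p + phi)


def bf_score(parents, model, reference, priors, p0=1e-7, fp_penalty=1.0,
             tol=1e-9, eps=1e-12):
    """Score a model (term -> m) against a reference (term -> r)."""

    def clamp(x):
        return min(max(x, eps), 1.0 - eps)

    score = clamp(p0)
    for term in sorted(model):
        m, r, b = model[term], reference[term], priors[term]
        m_cmp = 0 if abs(m - b) <= tol else (1 if m > b else -1)
        r_cmp = 0 if abs(r - b) <= tol else (1 if r > b else -1)
        if m_cmp == 0 or r_cmp == 0:
            continue
        mc, bc = clamp(m), clamp(b)
        if m_cmp > 0 and r_cmp > 0:  # TP
            tau, phi, alpha = mc, bc, bf_alpha(r, b)
        elif m_cmp < 0 and r_cmp < 0:  # TN
            tau, phi, alpha = 1 - mc, 1 - bc, bf_alpha(r, b)
        elif m_cmp < 0 and r_cmp > 0:  # FN
            tau, phi, alpha = 1 - bc, 1 - mc, bf_alpha(r, b)
        else:  # FP: nearest ancestor with reference above its own background
            dist = bf_ancestor_distances(parents, term)
            qualifying = [
                a for a in dist if reference[a] > priors[a] + tol
            ]
            if not qualifying:
                tau, phi, alpha = 1 - mc, 1 - bc, bf_alpha(r, b)
            else:
                anc = min(qualifying, key=lambda a: (dist[a], a))
                b_a = clamp(priors[anc])
                omega_t = (mc / (1 - mc)) * ((1 - bc) / bc)
                m_a = omega_t * b_a / ((omega_t - 1) * b_a + 1)
                beta = math.tanh(fp_penalty * math.log(b_a / bc)) if b_a > bc else 0.0
                beta = max(beta, 0.0)
                tau_a = (1 - beta) * m_a + beta * b_a
                phi_a = b_a
                tau = tau_a * (1 - mc)
                phi = phi_a * (1 - bc)
                alpha = bf_alpha(reference[anc], bc)
        tau = clamp(alpha * tau + (1 - alpha) * phi)
        phi = clamp(phi)
        score = bf_update(score, tau, phi)
    return score
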