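"""Independent brute-force reference implementation for oracle tests.

Everything here is deliberately written as plain nested loops over the
lattice, recomputing neighborhoods on the fly, with no code shared with the
package internals.  It follows the same documented RNG draw protocol as
``culturesim.dynamics`` so that a full timestep can be compared bit for bit
against the optimized implementation.
"""

from __future__ import annotations

import math

import numpy as np

EMPTY = -1


def _offsets(neighborhood):
    if neighborhood == "moore8":
        return [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    return [(-1, 0), (0, -1), (0, 1), (1, 0)]


def _neighbors(r, c, s, neighborhood, boundary):
    out = []
    for dr, dc in _offsets(neighborhood):
        rr, cc = r + dr, c + dc
        if boundary == "toroidal":
            out.append((rr % s, cc % s))
        elif 0 <= rr < s and 0 <= cc < s:
            out.append((rr, cc))
    return out


def _weight(freq, inp, selection_mode):
    if selection_mode == "distance":
        return 1.0 - abs(freq - inp)
    return 1.0 - max(0.0, freq - inp)


def reference_step(alive, culture, preference, next_culture_id, config, rng):
    """One full timestep (mortality, replacement, learning) by brute force.

    Operates on copies of the input arrays; returns
    ``(alive, culture, preference, next_culture_id)``.
    """
    s = alive.shape[0]
    alive = alive.copy()
    culture = culture.copy()
    preference = preference.copy()

    # --- mortality: one uniform draw per site, row-major ---
    u = rng.random(s * s)
    for r in range(s):
        for c in range(s):
            if alive[r, c] and u[r * s + c] < config.death_prob:
                alive[r, c] = False
                culture[r, c] = EMPTY

    # --- replacement: randomized order over ascending vacancy list ---
    vacancies = [(r, c) for r in range(s) for c in range(s) if not alive[r, c]]
    perm = rng.permutation(len(vacancies))
    juveniles = []
    for k in perm:
        r, c = vacancies[int(k)]
        cands = [
            (rr, cc)
            for rr, cc in _neighbors(r, c, s, config.neighborhood, config.boundary)
            if alive[rr, cc] and culture[rr, cc] != EMPTY
        ]
        if not cands:
            continue
        n = len(cands)
        counts = {}
        for rr, cc in cands:
            counts[culture[rr, cc]] = counts.get(culture[rr, cc], 0) + 1
        weights = [
            _weight(counts[culture[rr, cc]] / n, config.ideal_neighbor_proportion,
                    config.selection_mode)
            for rr, cc in cands
        ]
        total = sum(weights)
        if total > 0.0:
            target = rng.random() * total
            acc = 0.0
            parent = cands[-1]
            for cand, w in zip(cands, weights):
                acc += w
                if target < acc:
                    parent = cand
                    break
        else:
            parent = cands[int(rng.integers(n))]
        pref = int(preference[parent])
        if rng.random() < config.preference_mutation_prob:
            pref = int(rng.integers(2))
        alive[r, c] = True
        culture[r, c] = EMPTY
        preference[r, c] = pref
        juveniles.append(((r, c), pref))

    # --- learning: synchronous over the start-of-phase lattice ---
    frozen = culture.copy()
    for (r, c), pref in juveniles:
        tutors = [
            (rr, cc)
            for rr, cc in _neighbors(r, c, s, config.neighborhood, config.boundary)
            if alive[rr, cc] and frozen[rr, cc] != EMPTY
        ]
        if not tutors or rng.random() < config.invention_prob:
            culture[r, c] = next_culture_id
            next_culture_id += 1
            continue
        counts = {}
        for rr, cc in tutors:
            t = int(frozen[rr, cc])
            counts[t] = counts.get(t, 0) + 1
        n = len(tutors)
        if config.bias_mode == "strict":
            extreme = max(counts.values()) if pref == 0 else min(counts.values())
            tied = sorted(t for t, k in counts.items() if k == extreme)
            chosen = tied[0] if len(tied) == 1 else tied[int(rng.integers(len(tied)))]
        else:
            types = sorted(counts)
            if pref == 0:
                ws = [(counts[t] / n) ** 2 for t in types]
            else:
                ws = [1.0 - counts[t] / n for t in types]
            total = sum(ws)
            if total <= 0.0:
                chosen = types[int(rng.integers(len(types)))]
            else:
                target = rng.random() * total
                acc = 0.0
                chosen = types[-1]
                for t, w in zip(types, ws):
                    acc += w
                    if target < acc:
                        chosen = t
                        break
        culture[r, c] = chosen
    return alive, culture, preference, next_culture_id


def reference_sobel(alive, culture):
    """Sobel patchiness by direct double-loop 3x3 convolution with reflect
    padding, summed over all per-type indicator images."""
    kx = [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]
    ky = [[-1, -2, -1], [0, 0, 0], [1, 2, 1]]
    s = alive.shape[0]
    types = sorted({int(culture[r, c]) for r in range(s) for c in range(s)
                    if alive[r, c] and culture[r, c] != EMPTY})

    def reflect(i):
        # scipy 'reflect' mode: (d c b a | a b c d | d c b a)
        if i < 0:
            return -i - 1
        if i >= s:
            return 2 * s - i - 1
        return i

    total = 0.0
    for t in types:
        ind = [[1.0 if (alive[r, c] and culture[r, c] == t) else 0.0 for c in range(s)]
               for r in range(s)]
        for r in range(s):
            for c in range(s):
                gx = 0.0
                gy = 0.0
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        v = ind[reflect(r + dr)][reflect(c + dc)]
                        gx += kx[dr + 1][dc + 1] * v
                        gy += ky[dr + 1][dc + 1] * v
                total += math.hypot(gx, gy)
    return total
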