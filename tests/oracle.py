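"""Independent full-matrix Gotoh reference aligner for cross-checking.

Deliberately written with a different mechanism than the blocked engine:
plain per-cell Python loops over full H/E/F matrices with explicit traceback
pointers stored during the fill (the engine stores no pointers and replays
block interiors instead).  Shares the engine's tie-break contract — diagonal
over vertical over horizontal, gap closure over extension, first (smallest
(i, j)) local maximum — so alignments, not just scores, must agree.
"""

from __future__ import annotations

NEG = -(10 ** 15)

_DIAG, _FROM_F, _FROM_E = 0, 1, 2
_CLOSE, _EXTEND = 0, 1


def gotoh_align(sub, goa, gea, gob, geb, local=False):
    """Affine-gap DP over a precomputed substitution grid.

    ``sub`` is an la x lb integer grid; gap penalty sequences are indexed by
    the consumed residue.  Returns ``(score, moves, origin, end)`` with moves
    as 'D'/'U'/'L' in forward order.
    """
    la, lb = len(sub), len(sub[0]) if sub else 0
    H = [[0] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]
    ph = [[_DIAG] * (lb + 1) for _ in range(la + 1)]
    pe = [[_CLOSE] * (lb + 1) for _ in range(la + 1)]
    pf = [[_CLOSE] * (lb + 1) for _ in range(la + 1)]

    if not local:
        for j in range(1, lb + 1):
            E[0][j] = (H[0][j - 1] - gob[j - 1] if j == 1
                       else E[0][j - 1] - geb[j - 1])
            H[0][j] = E[0][j]
            pe[0][j] = _CLOSE if j == 1 else _EXTEND
            ph[0][j] = _FROM_E
        for i in range(1, la + 1):
            F[i][0] = (H[i - 1][0] - goa[i - 1] if i == 1
                       else F[i - 1][0] - gea[i - 1])
            H[i][0] = F[i][0]
            pf[i][0] = _CLOSE if i == 1 else _EXTEND
            ph[i][0] = _FROM_F

    best, bi, bj = 0, 0, 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            open_e = H[i][j - 1] - gob[j - 1]
            ext_e = E[i][j - 1] - geb[j - 1]
            if open_e >= ext_e:       # prefer closing the gap on ties
                E[i][j], pe[i][j] = open_e, _CLOSE
            else:
                E[i][j], pe[i][j] = ext_e, _EXTEND
            open_f = H[i - 1][j] - goa[i - 1]
            ext_f = F[i - 1][j] - gea[i - 1]
            if open_f >= ext_f:
                F[i][j], pf[i][j] = open_f, _CLOSE
            else:
                F[i][j], pf[i][j] = ext_f, _EXTEND
            diag = H[i - 1][j - 1] + sub[i - 1][j - 1]
            # Tie-break: diagonal > vertical (F) > horizontal (E).
            h, p = diag, _DIAG
            if F[i][j] > h:
                h, p = F[i][j], _FROM_F
            if E[i][j] > h:
                h, p = E[i][j], _FROM_E
            if local and h < 0:
                h, p = 0, _DIAG
            H[i][j], ph[i][j] = h, p
            if local and h > best:
                best, bi, bj = h, i, j

    if local:
        if best <= 0:
            return 0, [], (0, 0), (0, 0)
        i, j, end = bi, bj, (bi, bj)
        score = best
    else:
        i, j, end = la, lb, (la, lb)
        score = H[la][lb]

    moves = []
    state = "H"
    while True:
        if local and state == "H" and H[i][j] == 0:
            break
        if not local and i == 0 and j == 0:
            break
        if state == "H":
            p = ph[i][j]
            if p == _DIAG:
                moves.append("D")
                i -= 1
                j -= 1
            elif p == _FROM_F:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            moves.append("U")
            state = "H" if pf[i][j] == _CLOSE else "F"
            i -= 1
        else:
            moves.append("L")
            state = "H" if pe[i][j] == _CLOSE else "E"
            j -= 1
    moves.reverse()
    return score, moves, (i, j), end


def rescore_moves(moves, origin, sub, goa, gea, gob, geb):
    """Column-by-column affine rescoring of a move path (independent of any
    DP fill): diagonal adds the substitution score, the first gap move of a
    run pays open, later ones pay extend."""
    i, j = origin
    total = 0
    prev = None
    for mv in moves:
        if mv == "D":
            total += sub[i][j]
            i += 1
            j += 1
        elif mv == "U":
            total -= goa[i] if prev != "U" else gea[i]
            i += 1
        else:
            total -= gob[j] if prev != "L" else geb[j]
            j += 1
        prev = mv
    return total
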