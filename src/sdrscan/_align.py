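"""Affine-gap local alignment (Gotoh) with full traceback.

Desk-scale sequences only (<= a few kb per side). A gap of length L
costs open + L * extend (open charged once, extend per base). The
traceback emits run-length ops: '=' match, 'X' mismatch, 'I' gap in the
query (subject base unmatched), 'D' gap in the subject.
"""

from __future__ import annotations

from dataclasses import dataclass

NEG = float("-inf")


@dataclass
class LocalAlignment:
    score: float
    q_start: int  # 0-based half-open on the query
    q_end: int
    s_start: int  # 0-based half-open on the subject
    s_end: int
    ops: list  # [(op, run_length), ...] in query order

    @property
    def columns(self) -> int:
        return sum(n for _, n in self.ops)

    @property
    def matches(self) -> int:
        return sum(n for op, n in self.ops if op == "=")

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0

    @property
    def n_gaps(self) -> int:
        return sum(1 for op, _ in self.ops if op in "ID")

    @property
    def gap_bp_query(self) -> int:
        """Bases of the subject unmatched inside the alignment."""
        return sum(n for op, n in self.ops if op == "I")

    @property
    def gap_bp_subject(self) -> int:
        return sum(n for op, n in self.ops if op == "D")

    def match_runs(self):
        """Exact-match runs as (q_start, s_start, length), 0-based."""
        qi, si = self.q_start, self.s_start
        runs = []
        for op, n in self.ops:
            if op == "=":
                runs.append((qi, si, n))
            if op in "=X":
                qi += n
                si += n
            elif op == "I":
                si += n
            elif op == "D":
                qi += n
        return runs


def affine_fit_align(query: str, subject: str, match: float = 1,
                     mismatch: float = -2, gap_open: float = -5,
                     gap_extend: float = -2) -> LocalAlignment:
    """Fit (glocal) alignment: the whole query against a free-ended
    subject window.

    End-to-end in the query, so internal indels are always crossed —
    the right shape for comparing a sequence with its paralogous copy —
    while the subject's flanking context costs nothing.
    """
    n, m = len(query), len(subject)
    width = m + 1
    h_prev = [0.0] * width  # free subject prefix
    ptr_h = [bytearray(width) for _ in range(n + 1)]
    ptr_e = [bytearray(width) for _ in range(n + 1)]
    ptr_f = [bytearray(width) for _ in range(n + 1)]
    f_col = [NEG] * width

    for i in range(1, n + 1):
        qc = query[i - 1]
        h_cur = [0.0] * width
        h_cur[0] = gap_open + i * gap_extend  # deleted query prefix
        e = NEG
        ph, pe, pf = ptr_h[i], ptr_e[i], ptr_f[i]
        h_up = h_prev
        for j in range(1, m + 1):
            e_open = h_cur[j - 1] + gap_open + gap_extend
            e_ext = e + gap_extend
            if e_open >= e_ext:
                e, pe[j] = e_open, 0
            else:
                e, pe[j] = e_ext, 1
            f_open = h_up[j] + gap_open + gap_extend
            f_ext = f_col[j] + gap_extend
            if f_open >= f_ext:
                f_col[j], pf[j] = f_open, 0
            else:
                f_col[j], pf[j] = f_ext, 1
            diag = h_up[j - 1] + (match if qc == subject[j - 1] else mismatch)
            h, code = diag, 1
            if e > h:
                h, code = e, 2
            if f_col[j] > h:
                h, code = f_col[j], 3
            h_cur[j] = h
            ph[j] = code
        h_prev = h_cur

    bj = max(range(width), key=lambda j: h_prev[j])  # free subject suffix
    best = h_prev[bj]
    ops: list[list] = []

    def push(op):
        if ops and ops[-1][0] == op:
            ops[-1][1] += 1
        else:
            ops.append([op, 1])

    i, j, state = n, bj, "H"
    while i > 0:
        if j == 0:
            push("D")
            i -= 1
            continue
        if state == "H":
            code = ptr_h[i][j]
            if code == 1:
                push("=" if query[i - 1] == subject[j - 1] else "X")
                i -= 1
                j -= 1
            elif code == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            push("I")
            came_open = ptr_e[i][j] == 0
            j -= 1
            if came_open:
                state = "H"
        else:
            push("D")
            came_open = ptr_f[i][j] == 0
            i -= 1
            if came_open:
                state = "H"
    ops.reverse()
    return LocalAlignment(score=best, q_start=0, q_end=n,
                          s_start=j, s_end=bj, ops=[tuple(o) for o in ops])


def affine_local_align(query: str, subject: str, match: float = 1,
                       mismatch: float = -2, gap_open: float = -5,
                       gap_extend: float = -2) -> LocalAlignment:
    """Smith–Waterman with affine gaps and traceback."""
    n, m = len(query), len(subject)
    width = m + 1
    h_prev = [0.0] * width
    e_row = [NEG] * width
    # pointer rows, stored densely: one byte-code per cell
    # H: 0 stop, 1 diag, 2 from E (gap 'I'), 3 from F (gap 'D')
    ptr_h = [bytearray(width) for _ in range(n + 1)]
    ptr_e = [bytearray(width) for _ in range(n + 1)]  # 0 open, 1 extend
    ptr_f = [bytearray(width) for _ in range(n + 1)]
    f_col = [NEG] * width

    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        qc = query[i - 1]
        h_cur = [0.0] * width
        e = NEG
        ph, pe, pf = ptr_h[i], ptr_e[i], ptr_f[i]
        h_up = h_prev
        for j in range(1, m + 1):
            # E: gap in query (advance subject)
            e_open = h_cur[j - 1] + gap_open + gap_extend
            e_ext = e + gap_extend
            if e_open >= e_ext:
                e, pe[j] = e_open, 0
            else:
                e, pe[j] = e_ext, 1
            # F: gap in subject (advance query)
            f_open = h_up[j] + gap_open + gap_extend
            f_ext = f_col[j] + gap_extend
            if f_open >= f_ext:
                f_col[j], pf[j] = f_open, 0
            else:
                f_col[j], pf[j] = f_ext, 1
            diag = h_up[j - 1] + (match if qc == subject[j - 1] else mismatch)
            h = diag
            code = 1
            if e > h:
                h, code = e, 2
            if f_col[j] > h:
                h, code = f_col[j], 3
            if h <= 0:
                h, code = 0.0, 0
            h_cur[j] = h
            ph[j] = code
            if h > best:
                best, bi, bj = h, i, j
        h_prev = h_cur

    # traceback
    ops: list[list] = []

    def push(op):
        if ops and ops[-1][0] == op:
            ops[-1][1] += 1
        else:
            ops.append([op, 1])

    i, j = bi, bj
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            code = ptr_h[i][j]
            if code == 0:
                break
            if code == 1:
                push("=" if query[i - 1] == subject[j - 1] else "X")
                i -= 1
                j -= 1
            elif code == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            push("I")
            came_open = ptr_e[i][j] == 0
            j -= 1
            if came_open:
                state = "H"
        else:  # F
            push("D")
            came_open = ptr_f[i][j] == 0
            i -= 1
            if came_open:
                state = "H"
    ops.reverse()
    return LocalAlignment(score=best, q_start=i, q_end=bi,
                          s_start=j, s_end=bj,
                          ops=[tuple(o) for o in ops])
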