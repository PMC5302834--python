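"""Exact gap-filling: minimum completion size, exhaustive enumeration of all
cardinality-minimal completions, and their union / intersection.

Problem.  Given a draft network, a reference database, seeds and targets,
find the smallest sets R_fill of database reactions such that every
*reconstructable* target (one producible when the whole database is added)
lies in the topological scope of draft ∪ R_fill.  Because scope is monotone
in the reaction set, the maximal achievable target set is unique and is fixed
before minimisation (two-stage lexicographic objective).

Solving.  The producibility semantics is encoded as a mixed-integer linear
program with an acyclic-support scheme: a binary selection variable per
candidate database reaction, a firing variable per directed reaction, a
support arc per (reaction, product) pair and a continuous level per
metabolite.  Level ordering along chosen support arcs forbids circular
support, so MILP-feasibility coincides exactly with topological
producibility; cycles cannot self-start.  The program is solved with HiGHS
through scipy.optimize.milp at zero MIP gap, which makes the search exact.

Enumeration adds one exclusion cut per found optimum; union and intersection
are obtained by iterative constraint refinement (at most |union|, resp.
|solution|, additional solves) without enumerating the solution space.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .errors import SolverTimeout, TopofillError
from .network import CompletionResult, GapFillInstance, directed_view, merge_networks
from .producibility import compute_scope

__all__ = [
    "SolverOptions",
    "reconstructable_split",
    "min_completion_size",
    "enumerate_minimal_completions",
    "union_of_minimal",
    "intersection_of_minimal",
]


@dataclass(frozen=True)
class SolverOptions:
    """Knobs for the completion solver.

    enumeration_limit : cap on the number of returned solutions (None =
        exhaustive); when hit, results carry ``enumeration_truncated=True``.
    time_budget : overall wall-clock budget in seconds (None = unlimited).
    deterministic_order : sort solutions lexicographically by their sorted
        reaction ids, making output byte-stable.
    """

    enumeration_limit: int | None = None
    time_budget: float | None = None
    deterministic_order: bool = True

    def __post_init__(self):
        if self.enumeration_limit is not None and self.enumeration_limit < 1:
            raise ValueError("enumeration_limit must be >= 1")


def reconstructable_split(inst: GapFillInstance):
    """Partition targets into (reconstructable, unreconstructable).

    A target is reconstructable iff it is in the scope of seeds under
    draft ∪ database; by monotonicity of scope no subset of the database can
    produce anything more, so this is the unique maximal producible target
    set.
    """
    merged = merge_networks(inst.draft, inst.database)
    scope = compute_scope(directed_view(merged), inst.seeds)
    reconstructable = frozenset(inst.targets & scope.producible)
    return reconstructable, frozenset(inst.targets - reconstructable)


class _CompletionSolver:
    """One MILP encoding per instance, reused across solves."""

    def __init__(self, inst: GapFillInstance, opts: SolverOptions):
        self.inst = inst
        self.opts = opts
        self.deadline = (
            None if opts.time_budget is None else time.monotonic() + opts.time_budget
        )

        draft_dirs = directed_view(inst.draft)
        db_only = inst.database_only_ids
        db_net = inst.database.remove_reactions(
            set(inst.database.reactions) - db_only
        )
        db_dirs = directed_view(db_net)
        self.all_dirs = draft_dirs + db_dirs
        self.db_parents = {d.key: d.origin_id for d in db_dirs}

        full = compute_scope(self.all_dirs, inst.seeds)
        self.reconstructable = frozenset(inst.targets & full.producible)
        self.unreconstructable = frozenset(inst.targets - self.reconstructable)

        draft_scope = compute_scope(draft_dirs, inst.seeds)
        self.gap_targets = frozenset(self.reconstructable - draft_scope.producible)

        # prune to reactions that can ever fire and are backward-relevant
        fired = [d for d in self.all_dirs if d in full.fired]
        relevant_mets = set(self.gap_targets)
        kept: list = []
        changed = True
        taken = set()
        while changed:
            changed = False
            for d in fired:
                if d.key in taken:
                    continue
                if d.products & relevant_mets:
                    taken.add(d.key)
                    kept.append(d)
                    new = d.reactants - relevant_mets
                    if new:
                        relevant_mets |= new
                    changed = True
        self.kept = sorted(kept, key=lambda d: d.key)
        self.candidates = sorted(
            {self.db_parents[d.key] for d in self.kept if d.key in self.db_parents}
        )
        self._build_matrix()

    # -- encoding ----------------------------------------------------------
    def _build_matrix(self):
        seeds = self.inst.seeds
        mets = sorted(
            {m for d in self.kept for m in (d.reactants | d.products)} - seeds
        )
        n_x = len(self.candidates)
        n_z = len(self.kept)
        arcs = [
            (zi, m)
            for zi, d in enumerate(self.kept)
            for m in sorted(d.products)
            if m in set(mets)
        ]
        n_w = len(arcs)
        n_y = len(mets)
        self.n_x = n_x
        n_total = n_x + n_z + n_w + 2 * n_y
        xi = {r: i for i, r in enumerate(self.candidates)}
        yi = {m: n_x + n_z + n_w + i for i, m in enumerate(mets)}
        li = {m: n_x + n_z + n_w + n_y + i for i, m in enumerate(mets)}
        big_m = n_y + 1

        rows, cols, vals, ubs = [], [], [], []

        def row(entries, ub):
            r = len(ubs)
            for c, v in entries:
                rows.append(r)
                cols.append(c)
                vals.append(v)
            ubs.append(ub)

        for zi, d in enumerate(self.kept):
            zc = n_x + zi
            parent = self.db_parents.get(d.key)
            if parent is not None:
                row([(zc, 1.0), (xi[parent], -1.0)], 0.0)  # z <= x
            for m in sorted(d.reactants):
                if m not in seeds:
                    row([(zc, 1.0), (yi[m], -1.0)], 0.0)  # z <= y_reactant

        for wi, (zi, m) in enumerate(arcs):
            wc = n_x + n_z + wi
            row([(wc, 1.0), (n_x + zi, -1.0)], 0.0)  # w <= z
            for m2 in sorted(self.kept[zi].reactants):
                if m2 not in seeds:
                    # level(m) >= level(m2) + 1 when arc chosen
                    row([(li[m2], 1.0), (li[m], -1.0), (wc, big_m)], big_m - 1.0)

        by_met: dict[str, list[int]] = {}
        for wi, (zi, m) in enumerate(arcs):
            by_met.setdefault(m, []).append(n_x + n_z + wi)
        for m in mets:
            prods = by_met.get(m, [])
            row([(yi[m], 1.0)] + [(wc, -1.0) for wc in prods], 0.0)

        lb = np.zeros(n_total)
        ub = np.ones(n_total)
        ub[n_x + n_z + n_w + n_y:] = big_m  # levels
        for t in self.gap_targets:
            lb[yi[t]] = 1.0
        integrality = np.ones(n_total)
        integrality[n_x + n_z + n_w + n_y:] = 0.0

        self._A = csr_matrix(
            (vals, (rows, cols)), shape=(len(ubs), n_total)
        )
        self._ub_rows = np.asarray(ubs)
        self._lb = lb
        self._ub = ub
        self._integrality = integrality
        self._obj = np.zeros(n_total)
        self._obj[:n_x] = 1.0
        self._xi = xi

    # -- solving -----------------------------------------------------------
    def _remaining(self):
        if self.deadline is None:
            return None
        rem = self.deadline - time.monotonic()
        if rem <= 0:
            raise SolverTimeout("completion solver time budget exhausted")
        return rem

    def solve(self, cardinality=None, cuts=(), fix_zero=(), minimize=True):
        """One MILP solve.

        cuts: iterable of (reaction-id -> coeff, lb, ub) linear constraints
        over the candidate selection variables.  Returns the chosen reaction
        set, or None when infeasible.
        """
        lb = self._lb.copy()
        ub = self._ub.copy()
        for r in fix_zero:
            if r in self._xi:
                ub[self._xi[r]] = 0.0
        constraints = [LinearConstraint(self._A, -np.inf, self._ub_rows)]
        n_total = len(lb)
        if cardinality is not None:
            card = np.zeros(n_total)
            card[: self.n_x] = 1.0
            constraints.append(LinearConstraint(card, cardinality, cardinality))
        for coeffs, clo, chi in cuts:
            arr = np.zeros(n_total)
            for r, v in coeffs.items():
                if r in self._xi:
                    arr[self._xi[r]] = v
            constraints.append(LinearConstraint(arr, clo, chi))

        options = {"mip_rel_gap": 0.0}
        rem = self._remaining()
        if rem is not None:
            options["time_limit"] = rem
        res = milp(
            c=self._obj if minimize else np.zeros(n_total),
            constraints=constraints,
            integrality=self._integrality,
            bounds=Bounds(lb, ub),
            options=options,
        )
        if res.status == 2:  # infeasible
            return None
        if res.status == 1:  # time/iteration limit
            bound = getattr(res, "mip_dual_bound", None)
            raise SolverTimeout(
                "completion solver time budget exhausted",
                best_bound=None if bound is None else int(math.ceil(bound - 1e-6)),
            )
        if res.status != 0:
            raise TopofillError(f"MILP solver failed: {res.message}")
        chosen = frozenset(
            r for r, i in self._xi.items() if res.x[i] > 0.5
        )
        self._verify(chosen)
        return chosen

    def _verify(self, chosen: frozenset):
        keep = [
            d
            for d in self.all_dirs
            if self.db_parents.get(d.key) is None
            or self.db_parents[d.key] in chosen
        ]
        scope = compute_scope(keep, self.inst.seeds)
        if not self.reconstructable <= scope.producible:
            raise TopofillError(
                "internal error: MILP returned an unsound completion"
            )


def _solver(inst, opts):
    return _CompletionSolver(inst, opts or SolverOptions())


def min_completion_size(inst: GapFillInstance, opts: SolverOptions | None = None) -> int:
    """Least k such that some k-subset of the database makes every
    reconstructable target producible; 0 when nothing needs filling."""
    s = _solver(inst, opts)
    if not s.gap_targets:
        return 0
    sol = s.solve(minimize=True)
    if sol is None:  # cannot happen: full database is feasible by construction
        raise TopofillError("no completion found for reconstructable targets")
    return len(sol)


def enumerate_minimal_completions(
    inst: GapFillInstance, opts: SolverOptions | None = None
) -> CompletionResult:
    """All distinct cardinality-minimal completions (exhaustive unless
    ``enumeration_limit`` caps the list)."""
    opts = opts or SolverOptions()
    s = _solver(inst, opts)
    if not s.gap_targets:
        return CompletionResult(
            reconstructable=s.reconstructable,
            unreconstructable=s.unreconstructable,
            optimum_size=0,
            solutions=[frozenset()],
            union=frozenset(),
            intersection=frozenset(),
            enumeration_truncated=False,
        )
    first = s.solve(minimize=True)
    k = len(first)
    solutions = [first]
    truncated = False
    cuts = []
    while True:
        if opts.enumeration_limit is not None and len(solutions) >= opts.enumeration_limit:
            # is there anything left?
            cuts = [({r: 1.0 for r in sol}, -np.inf, k - 1) for sol in solutions]
            truncated = s.solve(cardinality=k, cuts=cuts, minimize=False) is not None
            break
        cuts = [({r: 1.0 for r in sol}, -np.inf, k - 1) for sol in solutions]
        nxt = s.solve(cardinality=k, cuts=cuts, minimize=False)
        if nxt is None:
            break
        solutions.append(nxt)
    if opts.deterministic_order:
        solutions.sort(key=lambda sol: sorted(sol))
    union = frozenset().union(*solutions) if solutions else frozenset()
    inter = solutions[0]
    for sol in solutions[1:]:
        inter = inter & sol
    return CompletionResult(
        reconstructable=s.reconstructable,
        unreconstructable=s.unreconstructable,
        optimum_size=k,
        solutions=solutions,
        union=union,
        intersection=frozenset(inter),
        enumeration_truncated=truncated,
    )


def union_of_minimal(inst: GapFillInstance, opts: SolverOptions | None = None):
    """Union over *all* cardinality-minimal completions (brave consequences),
    computed by iterative refinement: each solve must use at least one
    reaction outside the union found so far, so at most |union| solves."""
    s = _solver(inst, opts)
    if not s.gap_targets:
        return frozenset()
    first = s.solve(minimize=True)
    k = len(first)
    union = set(first)
    while True:
        outside = {r: 1.0 for r in s.candidates if r not in union}
        if not outside:
            break
        nxt = s.solve(cardinality=k, cuts=[(outside, 1.0, np.inf)], minimize=False)
        if nxt is None:
            break
        union |= nxt
    return frozenset(union)


def intersection_of_minimal(inst: GapFillInstance, opts: SolverOptions | None = None):
    """Intersection over all cardinality-minimal completions (cautious
    consequences): a reaction is in it iff forbidding that reaction makes the
    optimum worse.  Only members of one optimal solution need testing."""
    s = _solver(inst, opts)
    if not s.gap_targets:
        return frozenset()
    first = s.solve(minimize=True)
    k = len(first)
    inter = set()
    for r in sorted(first):
        if s.solve(cardinality=k, fix_zero=[r], minimize=False) is None:
            inter.add(r)
    return frozenset(inter)
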