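import itertools

import pytest

import dollotrace as dt


@pytest.fixture(scope="session")
def mammal_tree():
    return dt.load_fixture("mammal_tree")


@pytest.fixture(scope="session")
def krt24_states():
    return dt.load_fixture("krt24_states")


@pytest.fixture(scope="session")
def fig4_states():
    return dt.load_fixture("fig4_states")


@pytest.fixture(scope="session")
def tetrapod_maps():
    return dt.load_fixture("tetrapod_locus_maps")


@pytest.fixture(scope="session")
def pairing_rules():
    return dt.load_fixture("pairing_rules")


# ---------------------------------------------------------------------------
# independent oracles shared between unit and acceptance tests


def all_rooted_topologies(leaves):
    """Every rooted binary labelled topology on ``leaves`` as nested tuples."""
    leaves = list(leaves)
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for k in range(len(rest) + 1):
        for combo in itertools.combinations(rest, k):
            left = [first, *combo]
            right = [x for x in rest if x not in combo]
            if not right:
                continue
            for lt in all_rooted_topologies(left):
                for rt in all_rooted_topologies(right):
                    yield (lt, rt)


def topology_to_newick(top):
    if isinstance(top, str):
        return top
    return "(" + ",".join(topology_to_newick(c) for c in top) + ")"


def _nodes_edges(top):
    """(node ids, parent map, leaf-name map) of a nested-tuple topology."""
    nodes, parent, leaf_name = [], {}, {}
    counter = itertools.count()

    def walk(t, par):
        nid = next(counter)
        nodes.append(nid)
        if par is not None:
            parent[nid] = par
        if isinstance(t, str):
            leaf_name[nid] = t
        else:
            for child in t:
                walk(child, nid)

    walk(top, None)
    return nodes, parent, leaf_name


def brute_force_min_dollo_losses(top, column):
    """Minimum losses over every single-origin ancestral assignment.

    Enumerates all 0/1 labellings of the nodes of the nested-tuple
    topology ``top`` (leaves with a known state fixed, '?' leaves free),
    keeps those where the 1-nodes descend from a single origin (Dollo:
    at most one gain), and returns the smallest number of 1->0 edges.
    None when no valid assignment exists.
    """
    nodes, parent, leaf_name = _nodes_edges(top)
    fixed = {}
    free = []
    for nid in nodes:
        if nid in leaf_name:
            s = column.get(leaf_name[nid], "?")
            if s == "?":
                free.append(nid)
            else:
                fixed[nid] = s
        else:
            free.append(nid)
    best = None
    for bits in itertools.product((0, 1), repeat=len(free)):
        lab = dict(fixed)
        lab.update(zip(free, bits))
        origins = sum(
            1 for nid in nodes
            if lab[nid] == 1 and (nid not in parent or lab[parent[nid]] == 0)
        )
        if origins > 1:
            continue
        losses = sum(
            1 for nid, par in parent.items()
            if lab[par] == 1 and lab[nid] == 0
        )
        best = losses if best is None else min(best, losses)
    return best


def enumerate_mwu_two_sided(a, b):
    """Exact two-tailed Mann-Whitney p by full enumeration of labelings."""
    pooled = list(a) + list(b)
    na = len(a)
    idx = range(len(pooled))

    def u_stat(group_idx):
        g = [pooled[i] for i in group_idx]
        rest = [pooled[i] for i in idx if i not in set(group_idx)]
        return sum((x > y) + 0.5 * (x == y) for x in g for y in rest)

    u_obs = u_stat(range(na))
    us = [u_stat(c) for c in itertools.combinations(idx, na)]
    n = len(us)
    lo = sum(u <= u_obs for u in us) / n
    hi = sum(u >= u_obs for u in us) / n
    return min(1.0, 2 * min(lo, hi))
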