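import numpy as np
import pytest

from agepath.ontology import GoDag


@pytest.fixture
def chain_dag() -> GoDag:
    """C is_a A is_a R — the minimal chain."""
    terms = {t: {"name": t, "namespace": "biological_process", "obsolete": False}
             for t in ("R", "A", "C")}
    return GoDag(terms=terms, parents={"A": (("R", "is_a"),), "C": (("A", "is_a"),)})


@pytest.fixture
def sibling_dag() -> GoDag:
    """A and B are is_a children of root R."""
    terms = {t: {"name": t, "namespace": "biological_process", "obsolete": False}
             for t in ("R", "A", "B")}
    return GoDag(terms=terms, parents={"A": (("R", "is_a"),), "B": (("R", "is_a"),)})


@pytest.fixture
def diamond_dag() -> GoDag:
    """F reaches root R along two is_a paths (via X and via Y)."""
    terms = {t: {"name": t, "namespace": "biological_process", "obsolete": False}
             for t in ("R", "X", "Y", "F")}
    return GoDag(
        terms=terms,
        parents={
            "X": (("R", "is_a"),),
            "Y": (("R", "is_a"),),
            "F": (("X", "is_a"), ("Y", "is_a")),
        },
    )


def random_dag(rng: np.random.Generator, n_terms: int, p_extra: float = 0.3) -> GoDag:
    """Random single-namespace DAG: node i picks parents among earlier nodes."""
    terms = {f"T{i:03d}": {"name": f"T{i:03d}", "namespace": "biological_process",
                           "obsolete": False} for i in range(n_terms)}
    ids = sorted(terms)
    parents = {}
    for i in range(1, n_terms):
        links = [(ids[int(rng.integers(i))], "is_a")]
        if i > 1 and rng.random() < p_extra:
            extra = ids[int(rng.integers(i))]
            if extra != links[0][0]:
                rel = "part_of" if rng.random() < 0.5 else "is_a"
                links.append((extra, rel))
        parents[ids[i]] = tuple(sorted(set(links)))
    return GoDag(terms=terms, parents=parents)


def naive_svalues(dag: GoDag, focal: str, w_is_a: float = 0.8,
                  w_part_of: float = 0.6) -> dict[str, float]:
    """Per-path max enumeration of Wang S-values (independent oracle)."""
    best = {focal: 1.0}

    def walk(term: str, value: float) -> None:
        for parent, rel in dag.parents.get(term, ()):
            w = w_is_a if rel == "is_a" else w_part_of
            v = value * w
            if v > best.get(parent, 0.0):
                best[parent] = v
            walk(parent, v)

    walk(focal, 1.0)
    return best
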