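import numpy as np
import pytest

from funcomp import AnnotationIndex


@pytest.fixture
def toy_ann():
    """Four genes over three overlapping classes (the schematic example)."""
    return AnnotationIndex(
        {"g1": {"A1"}, "g2": {"A1", "A2"}, "g3": {"A2", "A3"}, "g4": {"A3"}},
        ["A1", "A2", "A3"],
    )


@pytest.fixture
def toy_genes():
    return ["g1", "g2", "g3", "g4"]


def random_annotation(rng: np.random.Generator, s: int, n_genes: int,
                      max_classes: int = 3, prefix: str = "g"):
    """Random AnnotationIndex: each gene gets 1..max_classes classes."""
    classes = [f"A{i}" for i in range(s)]
    mapping = {}
    for g in range(n_genes):
        size = int(rng.integers(1, min(max_classes, s) + 1))
        chosen = rng.choice(s, size=size, replace=False)
        mapping[f"{prefix}{g}"] = {classes[i] for i in chosen}
    return AnnotationIndex(mapping, classes)


def tilted_single_class_lists(s: int = 20, base: int = 10, tilt: int = 7):
    """Two lists with disjoint genes, one class per gene, alternating tilt.

    Gives a deterministic scenario where the per-class differences are
    individually weak but jointly strong: the global test rejects while no
    single class survives Holm adjustment.
    """
    classes = [f"A{i}" for i in range(s)]
    mapping, A, B = {}, [], []
    g = 0
    for i in range(s):
        for _ in range(base):
            mapping[f"a{g}"] = {classes[i]}
            A.append(f"a{g}")
            g += 1
    for i in range(s):
        count = base + (tilt if i % 2 == 0 else -tilt)
        for _ in range(count):
            mapping[f"b{g}"] = {classes[i]}
            B.append(f"b{g}")
            g += 1
    return A, B, AnnotationIndex(mapping, classes)
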