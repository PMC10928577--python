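import dendropy
import numpy as np
import pytest

from nutriphylo import (
    LandscapeSpec,
    render_contour_image,
    simulate_performance_points,
    simulate_tree,
)


def make_star_tree(n_tips: int, branch_length: float = 1.0) -> dendropy.Tree:
    """Rooted star phylogeny: every tip attaches directly to the root."""
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    for i in range(n_tips):
        ch = tree.seed_node.new_child(edge_length=branch_length)
        ch.taxon = tns.new_taxon(f"s{i + 1}")
    return tree


def make_two_tip_tree(shared: float, pendant: float = 1.0) -> dendropy.Tree:
    """((A, B) pair sharing a root branch of length ``shared``."""
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    inner = tree.seed_node.new_child(edge_length=shared)
    for lab in ("A", "B"):
        ch = inner.new_child(edge_length=pendant)
        ch.taxon = tns.new_taxon(lab)
    # a third tip keeps the tree non-degenerate for covariance checks
    ch = tree.seed_node.new_child(edge_length=shared + pendant)
    ch.taxon = tns.new_taxon("C")
    return tree


@pytest.fixture(scope="session")
def yule_tree_50() -> dendropy.Tree:
    return simulate_tree(50, seed=1)


@pytest.fixture(scope="session")
def gaussian_spec() -> LandscapeSpec:
    return LandscapeSpec(peak_p=3.0, peak_c=1.0, peak_height=10.0, baseline=50.0,
                         width_p=1.0, width_c=1.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def gaussian_points(gaussian_spec):
    return simulate_performance_points(gaussian_spec)


@pytest.fixture(scope="session")
def default_points():
    return simulate_performance_points(LandscapeSpec())


@pytest.fixture(scope="session")
def rendered(default_points):
    return render_contour_image(default_points, n_bands=5, image_size=(200, 200))
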