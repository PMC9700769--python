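import numpy as np
import pytest

from cordnet.synthetic import SyntheticNetworkSpec


def make_disk(shape=(64, 64), center=(32, 32), radius=10):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def make_annulus(shape=(64, 64), center=(32, 32), r_out=20, r_in=10):
    d2 = make_disk(shape, center, r_out)
    return d2 & ~make_disk(shape, center, r_in - 1)


def random_closed_mask(rng, shape=(64, 64), p=0.45):
    """Bernoulli field smoothed by morphological closing: a dense blobby
    mask with nontrivial components and holes."""
    from scipy import ndimage as ndi

    m = rng.random(shape) < p
    return ndi.binary_closing(m, structure=np.ones((3, 3), dtype=bool))


def flood_fill_euler(mask):
    """Independent (n_components, n_holes) oracle: plain Python BFS with
    8-connected foreground and 4-connected background."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape

    def components(cells, neigh):
        seen = set()
        comps = []
        for c in cells:
            if c in seen:
                continue
            comp = {c}
            seen.add(c)
            stack = [c]
            while stack:
                r0, c0 = stack.pop()
                for dr, dc in neigh:
                    q = (r0 + dr, c0 + dc)
                    if q in cells and q not in seen:
                        seen.add(q)
                        comp.add(q)
                        stack.append(q)
            comps.append(comp)
        return comps

    n8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    n4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    fg = {tuple(p) for p in np.argwhere(mask)}
    bg = {tuple(p) for p in np.argwhere(~mask)}
    n_comp = len(components(fg, n8))
    holes = sum(
        1
        for comp in components(bg, n4)
        if not any(r in (0, h - 1) or c in (0, w - 1) for r, c in comp)
    )
    return n_comp, holes


@pytest.fixture
def noise_free_spec():
    return SyntheticNetworkSpec(
        n_seeds=25, rng_seed=11, noise_sd=0.0, illumination_amplitude=0.0
    )
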