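import numpy as np
import pytest

from ohcinfluence.threads import Thread, build_reply_tree

AUTHOR_POOL = ["u1", "u2", "u3", "u4"]


def random_thread(rng: np.random.Generator, max_posts: int = 30) -> Thread:
    """A random valid indent sequence with a small author pool, so author
    coincidences (and hence relationship triples) actually occur."""
    n = int(rng.integers(1, max_posts + 1))
    records = []
    max_depth = 0
    for i in range(n):
        author = AUTHOR_POOL[rng.integers(len(AUTHOR_POOL))]
        if i == 0:
            depth = 0
        else:
            depth = int(rng.integers(1, max_depth + 2))
        max_depth = max(max_depth, depth)
        records.append((author, depth, f"post number {i} text."))
    return build_reply_tree(records, thread_id="rand")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
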