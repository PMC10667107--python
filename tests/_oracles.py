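"""Independent brute-force oracles used by the test suite only."""

import numpy as np


def max_matching_bruteforce(a: np.ndarray, b: np.ndarray, max_dist: float) -> int:
    """Exact maximum one-to-one matching size via augmenting-path search.

    Kuhn's algorithm on the bipartite graph of admissible (distance strictly
    below ``max_dist``) candidate pairs — independent of the package's
    assignment-based implementation.
    """
    na, nb = len(a), len(b)
    adj = [
        [j for j in range(nb) if np.linalg.norm(a[i] - b[j]) < max_dist]
        for i in range(na)
    ]
    match_of_b = [-1] * nb

    def try_augment(i: int, visited: list[bool]) -> bool:
        for j in adj[i]:
            if not visited[j]:
                visited[j] = True
                if match_of_b[j] == -1 or try_augment(match_of_b[j], visited):
                    match_of_b[j] = i
                    return True
        return False

    size = 0
    for i in range(na):
        if try_augment(i, [False] * nb):
            size += 1
    return size
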