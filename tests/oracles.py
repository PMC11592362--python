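"""Independent brute-force oracles shared by the test modules."""


def dcor_bruteforce(x, y):
    """Literal double-centring distance correlation: explicit loops, no numpy."""
    n = len(x)
    a = [[abs(x[i] - x[j]) for j in range(n)] for i in range(n)]
    b = [[abs(y[i] - y[j]) for j in range(n)] for i in range(n)]

    def center(m):
        row = [sum(m[i]) / n for i in range(n)]
        col = [sum(m[i][j] for i in range(n)) / n for j in range(n)]
        grand = sum(sum(r) for r in m) / n**2
        return [[m[i][j] - row[i] - col[j] + grand for j in range(n)] for i in range(n)]

    A, B = center(a), center(b)
    dcov2 = sum(A[i][j] * B[i][j] for i in range(n) for j in range(n)) / n**2
    dvarx = sum(A[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    dvary = sum(B[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    if dvarx <= 0 or dvary <= 0:
        return 0.0
    return (max(dcov2, 0.0) / (dvarx * dvary) ** 0.5) ** 0.5
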