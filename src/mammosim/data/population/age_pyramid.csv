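birth_year,weight
1930,0.010234
1931,0.01038
1932,0.010526
1933,0.010673
1934,0.010819
1935,0.010965
1936,0.011111
1937,0.011257
1938,0.011404
1939,0.01155
1940,0.011696
1941,0.011842
1942,0.011988
1943,0.012135
1944,0.012281
1945,0.012427
1946,0.012573
1947,0.012719
1948,0.012865
1949,0.013012
1950,0.013158
1951,0.013304
1952,0.01345
1953,0.013596
1954,0.013743
1955,0.013889
1956,0.014035
1957,0.014181
1958,0.014327
1959,0.014474
1960,0.01462
1961,0.014656
1962,0.014693
1963,0.01473
1964,0.014766
1965,0.014803
1966,0.014839
1967,0.014876
1968,0.014912
1969,0.014949
1970,0.014985
1971,0.015022
1972,0.015058
1973,0.015095
1974,0.015132
1975,0.015168
1976,0.015205
1977,0.015241
1978,0.015278
1979,0.015314
1980,0.015351
1981,0.015387
1982,0.015424
1983,0.015461
1984,0.015497
1985,0.015534
1986,0.01557
1987,0.015607
1988,0.015643
1989,0.01568
1990,0.015716
1991,0.015753
1992,0.015789
1993,0.015826
1994,0.015863
1995,0.015899
1996,0.015936
1997,0.015972
1998,0.016009
1999,0.016045
2000,0.016082
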