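year,ppm
1959,315.97
1960,316.91
1961,317.64
1962,318.45
1963,318.99
1964,319.62
1965,320.04
1966,321.37
1967,322.18
1968,323.05
1969,324.62
1970,325.68
1971,326.32
1972,327.46
1973,329.68
1974,330.19
1975,331.12
1976,332.03
1977,333.84
1978,335.41
1979,336.84
1980,338.76
1981,340.12
1982,341.48
1983,343.15
1984,344.87
1985,346.35
1986,347.61
1987,349.31
1988,351.69
1989,353.20
1990,354.45
1991,355.70
1992,356.54
1993,357.21
1994,358.96
1995,360.97
1996,362.74
1997,363.88
1998,366.84
1999,368.54
2000,369.71
2001,371.32
2002,373.45
2003,375.98
2004,377.70
2005,379.98
2006,382.09
2007,384.02
2008,385.83
2009,387.64
2010,390.10
2011,391.85
2012,394.06
2013,396.74
2014,398.81
2015,401.01
2016,404.41
2017,406.76
2018,408.72
2019,411.65
2020,414.21
2021,416.41
2022,418.53
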