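# Rook-contiguity adjacency of China's 31 provincial-level regions.
# Hainan (an island) is assigned Guangdong, its nearest mainland province,
# as its sole neighbour, so that the weight matrix has no empty rows.
# Columns: region number, region name, adjacent region numbers.
1	Beijing	2 3
2	Tianjin	1 3 15
3	Hebei	1 2 4 5 6 15 16
4	Shanxi	3 5 16 27
5	Neimenggu	3 4 6 7 8 27 28 30
6	Liaoning	3 5 7
7	Jilin	5 6 8
8	Heilongjiang	5 7
9	Shanghai	10 11
10	Jiangsu	9 11 12 15
11	Zhejiang	9 10 12 13 14
12	Anhui	10 11 14 15 16 17
13	Fujian	11 14 19
14	Jiangxi	11 12 13 17 18 19
15	Shandong	2 3 10 12 16
16	Henan	3 4 12 15 17 27
17	Hubei	12 14 16 18 22 27
18	Hunan	14 17 19 20 22 24
19	Guangdong	13 14 18 20 21
20	Guangxi	18 19 24 25
21	Hainan	19
22	Sichuan	17 18 23 24 27
23	Chongqing	22 24 25 26 27 28 29
24	Guizhou	18 20 22 23 25
25	Yunnan	20 23 24 26
26	Tibet	23 25 29 31
27	Shaanxi	4 5 16 17 22 23 28 30
28	Gansu	5 23 27 29 30 31
29	Qinghai	23 26 28 31
30	Ningxia	5 27 28
31	Xinjiang	26 28 29
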