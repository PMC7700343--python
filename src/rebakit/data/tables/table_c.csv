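score_a,score_b,score_c
1,1,1
1,2,1
1,3,1
1,4,2
1,5,3
1,6,3
1,7,4
1,8,5
1,9,6
1,10,7
1,11,7
1,12,7
2,1,1
2,2,2
2,3,2
2,4,3
2,5,4
2,6,4
2,7,5
2,8,6
2,9,6
2,10,7
2,11,7
2,12,8
3,1,2
3,2,3
3,3,3
3,4,3
3,5,4
3,6,5
3,7,6
3,8,7
3,9,7
3,10,8
3,11,8
3,12,8
4,1,3
4,2,4
4,3,4
4,4,4
4,5,5
4,6,6
4,7,7
4,8,8
4,9,8
4,10,9
4,11,9
4,12,9
5,1,4
5,2,4
5,3,4
5,4,5
5,5,6
5,6,7
5,7,8
5,8,8
5,9,9
5,10,9
5,11,9
5,12,9
6,1,6
6,2,6
6,3,6
6,4,7
6,5,8
6,6,8
6,7,9
6,8,9
6,9,10
6,10,10
6,11,10
6,12,10
7,1,7
7,2,7
7,3,7
7,4,8
7,5,9
7,6,9
7,7,9
7,8,10
7,9,10
7,10,11
7,11,11
7,12,11
8,1,8
8,2,8
8,3,8
8,4,9
8,5,10
8,6,10
8,7,10
8,8,10
8,9,10
8,10,11
8,11,11
8,12,11
9,1,9
9,2,9
9,3,9
9,4,10
9,5,10
9,6,10
9,7,11
9,8,11
9,9,11
9,10,12
9,11,12
9,12,12
10,1,10
10,2,10
10,3,10
10,4,11
10,5,11
10,6,11
10,7,11
10,8,12
10,9,12
10,10,12
10,11,12
10,12,12
11,1,11
11,2,11
11,3,11
11,4,11
11,5,12
11,6,12
11,7,12
11,8,12
11,9,12
11,10,12
11,11,12
11,12,12
12,1,12
12,2,12
12,3,12
12,4,12
12,5,12
12,6,12
12,7,12
12,8,12
12,9,12
12,10,12
12,11,12
12,12,12
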