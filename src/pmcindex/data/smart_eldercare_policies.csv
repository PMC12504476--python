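policy,name,organ,date,level
P1,National Plan for the Development of the Aging Career and the Older Adults Service System in the 14th Five-Year Plan,State Council (PRC),2021-12-30,central
P2,Opinions on Promoting the Development of Older Adults Services,State Council Office of the People's Republic of China,2019-04-16,central
P3,Regulations on Older Adults Services in Anhui Province,Anhui Provincial People's Congress,2022-09-29,provincial
P4,Regulations on the Promotion of Social Services for the Older Adults in Zhejiang Province,Zhejiang Provincial People's Congress,2021-09-30,provincial
P5,Regulations on Older Adults Services in Hainan Province,Hainan Provincial People's Congress,2023-05-24,provincial
P6,Shandong Province's 14th Five-Year Plan for Old-Age Service Systems,Shandong Provincial People's Government,2021-07-29,provincial
P7,Regulations on Home-based Older Adults Services in Yangzhou City,Yangzhou Municipal People's Congress,2021-06-08,municipal
P8,Regulation on the Promotion of Older Adults Services in Tianjin,Tianjin Municipal People's Congress,2020-12-01,municipal
P9,Regulations on Older Adults Services in Shanghai,Shanghai Municipal People's Congress,2023-12-18,municipal
P10,Regulations on the Promotion of Home-based Older Adults Services in the Zhuhai Special Economic Zone,Zhuhai People's Congress,2022-12-02,municipal
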