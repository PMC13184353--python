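scale,item,domain,reverse,stem
AMI,AMI-1,Emotional,1,feel sad or upset when hearing bad news
AMI,AMI-2,Social,1,start conversations with random people
AMI,AMI-3,Social,1,enjoy doing things with a few close friends
AMI,AMI-4,Social,1,suggest activities for me and my friends
AMI,AMI-5,Behavioural,1,make decisions firmly and without hesitation
AMI,AMI-6,Emotional,0,feel bad when an acquaintance has an accident or illness
AMI,AMI-7,Emotional,1,care about how my loved ones think of me
AMI,AMI-8,Social,1,go out with friends on a weekly basis
AMI,AMI-9,Behavioural,1,able to make an effort easily once decided
AMI,AMI-10,Behavioural,1,do not like to laze around
AMI,AMI-11,Behavioural,0,need reminders from others to get things done
AMI,AMI-12,Behavioural,1,motivated to see things through to the end
AMI,AMI-13,Emotional,1,feel awful after saying something insensitive
AMI,AMI-14,Social,1,start conversations without being prompted
AMI,AMI-15,Behavioural,1,do what I need to do straightaway
AMI,AMI-16,Emotional,1,feel moved by others' misfortune
AMI,AMI-17,Social,1,enjoy doing things with people I have just met
AMI,AMI-18,Emotional,1,emotions affected by those around me
AES,AES-1,Cognitive,1,interested in things
AES,AES-2,Behavioural,1,get things done during the day
AES,AES-3,Cognitive,1,getting things started on my own is important
AES,AES-4,Cognitive,1,interested in having new experiences
AES,AES-5,Cognitive,1,interested in learning new things
AES,AES-6,Behavioural,0,put little effort into anything
AES,AES-7,Emotional,1,approach life with intensity
AES,AES-8,Behavioural,1,seeing a job through to the end is important
AES,AES-9,Cognitive,1,spend time doing things that interest me
AES,AES-10,Behavioural,0,someone has to tell me what to do each day
AES,AES-11,Emotional,0,less concerned about my problems than I should be
AES,AES-12,Social,1,have friends
AES,AES-13,Social,1,getting together with friends is important
AES,AES-14,Emotional,1,get excited when something good happens
AES,AES-15,Cognitive,1,accurate understanding of my problems
AES,AES-16,Behavioural,1,getting things done during the day is important
AES,AES-17,Behavioural,1,have initiative
AES,AES-18,Behavioural,1,have motivation
DAS,DAS-1,Executive,0,need a bit of encouragement to get things started
DAS,DAS-2,Emotional,0,feel indifferent to what is going on around me
DAS,DAS-3,Initiation,1,think of new things to do during the day
DAS,DAS-4,Executive,1,able to organise several things at once
DAS,DAS-5,Emotional,0,express my feelings less than before
DAS,DAS-6,Initiation,1,contact my friends
DAS,DAS-7,Executive,1,able to focus on a task until it is finished
DAS,DAS-8,Emotional,0,feel emotionally flat
DAS,DAS-9,Initiation,1,make plans for the future
DAS,DAS-10,Executive,1,keep track of several tasks at the same time
DAS,DAS-11,Emotional,0,unconcerned about how others feel
DAS,DAS-12,Initiation,1,start new activities of my own accord
DAS,DAS-13,Executive,1,plan my activities in advance
DAS,DAS-14,Emotional,1,feel warmth towards people close to me
DAS,DAS-15,Initiation,1,set goals for myself
DAS,DAS-16,Executive,1,think ahead about the consequences of my actions
DAS,DAS-17,Emotional,1,moved by emotional events
DAS,DAS-18,Initiation,1,keep myself busy
DAS,DAS-19,Executive,1,concentrate on what I am doing
DAS,DAS-20,Emotional,0,react less strongly to good news than others do
DAS,DAS-21,Initiation,1,take up new interests
DAS,DAS-22,Executive,1,finish tasks without being distracted
DAS,DAS-23,Emotional,1,show my feelings openly
DAS,DAS-24,Initiation,1,get going on my own with everyday chores
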